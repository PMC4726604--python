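"""Mask rules, normalized histograms and the five summary metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtiprog.histogram import (DIFFUSIVITY_SPEC, FA_SPEC, EmptyTissueClassError,
                               HistogramSpec, build_masks, extract_values,
                               normalized_histogram, spec_for, summarize)
from dtiprog.synthetic import PhantomSpec, phantom_labels, simulate_phantom_visit


def brute_force_metrics(values, lower, upper, n_bins):
    """First-principles recomputation: explicit sort and moment sums."""
    inside = sorted(v for v in values if lower <= v <= upper)
    n = len(inside)
    if n % 2:
        median = inside[n // 2]
    else:
        median = (inside[n // 2 - 1] + inside[n // 2]) / 2
    width = (upper - lower) / n_bins
    counts = [0] * n_bins
    for v in inside:
        idx = min(int((v - lower) / width), n_bins - 1)
        counts[idx] += 1
    peak_bin = max(range(n_bins), key=lambda i: (counts[i], -i))
    peak_height = counts[peak_bin] / n
    peak_value = lower + (peak_bin + 0.5) * width
    mean = sum(inside) / n
    m2 = sum((v - mean) ** 2 for v in inside) / n
    m3 = sum((v - mean) ** 3 for v in inside) / n
    m4 = sum((v - mean) ** 4 for v in inside) / n
    skew = m3 / m2**1.5
    kurt = m4 / m2**2 - 3
    return median, peak_value, peak_height, skew, kurt


class TestBuildMasks:
    def _maps(self, nawm_prob, md_value):
        shape = (2, 2, 2)
        probs = {k: np.zeros(shape) for k in ("GM", "NAWM", "WMH", "CSF")}
        probs["NAWM"][0, 0, 0] = nawm_prob
        md = np.full(shape, 1e-3)
        md[0, 0, 0] = md_value
        return probs, md

    def test_csf_contaminated_voxel_excluded(self):
        probs, md = self._maps(0.6, 0.003)
        assert not build_masks(probs, md).nawm[0, 0, 0]

    def test_normal_wm_voxel_included(self):
        probs, md = self._maps(0.6, 0.001)
        assert build_masks(probs, md).nawm[0, 0, 0]

    def test_probability_tie_excluded(self):
        probs, md = self._maps(0.5, 0.001)
        assert not build_masks(probs, md).nawm[0, 0, 0]

    def test_csf_mask_keeps_high_md_voxels(self):
        shape = (2, 2, 2)
        probs = {k: np.zeros(shape) for k in ("GM", "NAWM", "WMH", "CSF")}
        probs["CSF"][:] = 0.9
        masks = build_masks(probs, np.full(shape, 0.003))
        assert masks.csf.all()

    def test_probabilities_outside_unit_interval_rejected(self):
        probs, md = self._maps(1.2, 0.001)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_masks(probs, md)

    def test_phantom_masks_match_label_enumeration(self, small_phantom_spec):
        """Noiseless probabilities reproduce the ground-truth labels minus
        the MD > 0.0026 removals, voxel count checked by enumeration."""
        maps, probs = simulate_phantom_visit(small_phantom_spec, None, 0, seed=3)
        labels = phantom_labels(small_phantom_spec, 0, seed=3)
        masks = build_masks(probs, maps["MD"].data)
        for lab, name in ((2, "nawm"), (3, "wmh"), (1, "gm")):
            expected = int(((labels == lab) & ~(maps["MD"].data > 0.0026)).sum())
            assert int(getattr(masks, name).sum()) == expected
        assert int(masks.csf.sum()) == int((labels == 4).sum())
        np.testing.assert_array_equal(masks.all_wm, masks.nawm | masks.wmh)


class TestExtractValues:
    def test_full_mask_returns_everything(self, rng):
        vol = rng.normal(size=(4, 4, 4))
        vals = extract_values(np.ones_like(vol, dtype=bool), vol)
        np.testing.assert_array_equal(np.sort(vals), np.sort(vol.ravel()))

    def test_empty_mask_signals(self):
        with pytest.raises(EmptyTissueClassError):
            extract_values(np.zeros((2, 2, 2), dtype=bool), np.ones((2, 2, 2)))

    def test_checkerboard_mask_takes_half(self):
        vol = np.arange(64, dtype=float).reshape(4, 4, 4)
        idx = np.indices(vol.shape).sum(axis=0)
        mask = idx % 2 == 0
        vals = extract_values(mask, vol)
        assert vals.size == 32
        np.testing.assert_array_equal(np.sort(vals), np.sort(vol[mask]))


class TestNormalizedHistogram:
    def test_point_mass_single_bin(self):
        h = normalized_histogram(np.full(100, 0.3), FA_SPEC)
        assert h.frequencies.max() == pytest.approx(1.0)
        assert (h.frequencies > 0).sum() == 1

    def test_diffusivity_bin_width(self):
        assert DIFFUSIVITY_SPEC.bin_width == pytest.approx(4e-6, rel=1e-12)
        assert FA_SPEC.bin_width == pytest.approx(0.001, rel=1e-12)

    def test_uniform_draws_peak_near_expected_frequency(self, rng):
        h = normalized_histogram(rng.uniform(0, 1, 10**6), FA_SPEC)
        # multinomial expectation 1/1000 per bin
        assert h.frequencies.max() == pytest.approx(0.001, abs=2e-4)
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_counted(self):
        h = normalized_histogram(np.array([0.5, 1.5, -0.2]), FA_SPEC)
        assert h.n_excluded == 2
        assert h.n_in_range == 1

    def test_no_in_range_values_signals(self):
        with pytest.raises(EmptyTissueClassError):
            normalized_histogram(np.array([5.0, 6.0]), FA_SPEC)


class TestSummarize:
    def test_symmetric_sample(self):
        s = summarize(np.array([0.2, 0.3, 0.4]), FA_SPEC)
        assert s.skew == pytest.approx(0.0, abs=1e-12)
        assert s.median == pytest.approx(0.3)

    def test_gaussian_excess_kurtosis_vanishes(self, rng):
        vals = np.clip(rng.normal(0.5, 0.05, 10**5), 0, 1)
        s = summarize(vals, FA_SPEC)
        assert s.kurtosis == pytest.approx(0.0, abs=0.05)

    def test_matches_brute_force_on_fixed_sample(self, rng):
        """All five metrics equal a first-principles recomputation."""
        vals = rng.uniform(0.0, 0.004, 50)
        spec = spec_for("MD")
        s = summarize(vals, spec)
        med, pv, ph, sk, ku = brute_force_metrics(vals, 0.0, 0.004, 1000)
        assert s.median == pytest.approx(med, abs=1e-15)
        assert s.peak_value == pytest.approx(pv, abs=1e-15)
        assert s.peak_height == pytest.approx(ph, abs=1e-15)
        assert s.skew == pytest.approx(sk, abs=1e-12)
        assert s.kurtosis == pytest.approx(ku, abs=1e-12)

    def test_constant_sample_flagged_degenerate(self):
        s = summarize(np.full(10, 0.4), FA_SPEC)
        assert s.degenerate
        assert np.isnan(s.skew) and np.isnan(s.kurtosis)

    def test_median_invariant_to_bin_count(self, rng):
        vals = rng.uniform(0, 1, 1000)
        s1 = summarize(vals, FA_SPEC)
        s2 = summarize(vals, HistogramSpec("FA", 0.0, 1.0, 10))
        assert s1.median == s2.median

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=3, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, random):
        vals = np.asarray(values)
        s1 = summarize(vals, FA_SPEC)
        shuffled = list(values)
        random.shuffle(shuffled)
        s2 = summarize(np.asarray(shuffled), FA_SPEC)
        assert s1.as_dict() == pytest.approx(s2.as_dict(), nan_ok=True)

    def test_all_wm_equals_concatenated_nawm_wmh(self, small_phantom_spec):
        maps, probs = simulate_phantom_visit(small_phantom_spec, None, 1, seed=9)
        masks = build_masks(probs, maps["MD"].data)
        spec = spec_for("MD")
        combined = summarize(extract_values(masks.all_wm, maps["MD"]), spec)
        concat = summarize(
            np.concatenate([extract_values(masks.nawm, maps["MD"]),
                            extract_values(masks.wmh, maps["MD"])]), spec)
        assert combined.as_dict() == pytest.approx(concat.as_dict())

    def test_broader_right_shifted_mixture_flattens_histogram(self, rng):
        """An MD-like progression (mixing in a broader, right-shifted
        component) lowers the peak and moves the median right."""
        base = rng.normal(8e-4, 6e-5, 40000)
        mixed = np.concatenate([
            base[:30000], rng.normal(1.3e-3, 3e-4, 10000)])
        spec = spec_for("MD")
        s0, s1 = summarize(base, spec), summarize(mixed, spec)
        assert s1.peak_height < s0.peak_height
        assert s1.median > s0.median
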