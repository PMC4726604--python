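"""Cohort and phantom generators: known truth, dropout, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtiprog.presets import svd_cohort_config
from dtiprog.synthetic import (DEFAULT_RETENTION, CohortConfig, MetricTruth,
                               PhantomSpec, eigenvalues_from_fa_md,
                               gradient_scheme, simulate_dwi,
                               simulate_metric_table, simulate_phantom_visit)
from dtiprog.tensor import TensorField


def metric_cfg(**kw):
    defaults = dict(beta0=1.0, beta1=-0.1)
    defaults.update(kw)
    return {"m": MetricTruth(**defaults)}


class TestMetricTable:
    def test_noise_free_line(self):
        cfg = CohortConfig(n_subjects=5, metrics=metric_cfg(), seed=0,
                           time_jitter=0.0)
        t = simulate_metric_table(cfg)
        for v, expected in enumerate((1.0, 0.9, 0.8, 0.7)):
            got = t[t.visit == v].value
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_dropout_counts_match_cohort_pattern(self):
        """Retention (99,96,74,68)/99 yields exactly those row counts."""
        cfg = svd_cohort_config(n_subjects=99, seed=4)
        t = simulate_metric_table(cfg)
        counts = t[t.metric == "All_WM:FA:median"].groupby("visit").size()
        assert list(counts) == [99, 96, 74, 68]

    def test_row_counts_monotone_nonincreasing(self):
        cfg = CohortConfig(n_subjects=50, metrics=metric_cfg(sd_resid=0.1),
                           retention=(1.0, 0.8, 0.8, 0.3), seed=1)
        counts = simulate_metric_table(cfg).groupby("visit").size()
        assert (np.diff(counts) <= 0).all()

    def test_per_subject_ols_slope_variance(self):
        """Var(subject OLS slope) = sd_slope^2 + sd_resid^2 / Sxx, with
        Sxx = 5 for visits 0..3 (oracle: empirical variance at n=2000)."""
        cfg = CohortConfig(
            n_subjects=2000,
            metrics=metric_cfg(sd_slope=0.5, sd_resid=1.0),
            seed=7, time_jitter=0.0)
        t = simulate_metric_table(cfg)
        slopes = (
            t.groupby("subject_id")
            .apply(lambda d: np.polyfit(d.time_years, d.value, 1)[0],
                   include_groups=False)
        )
        expected = 0.25 + 1.0 / 5.0
        se = expected * np.sqrt(2 / (len(slopes) - 1))
        assert abs(slopes.var(ddof=1) - expected) < 3 * se

    def test_same_seed_bit_identical(self):
        cfg = svd_cohort_config(n_subjects=20, seed=11)
        pd.testing.assert_frame_equal(simulate_metric_table(cfg),
                                      simulate_metric_table(cfg))

    def test_baseline_time_exact_followups_jittered(self):
        cfg = CohortConfig(n_subjects=30, metrics=metric_cfg(sd_resid=0.1),
                           seed=2, time_jitter=0.1)
        t = simulate_metric_table(cfg)
        assert (t[t.visit == 0].time_years == 0).all()
        follow = t[t.visit > 0]
        assert (np.abs(follow.time_years - follow.visit) <= 0.1 + 1e-12).all()
        assert follow.time_years.nunique() > 3

    def test_informative_dropout_tilts_toward_steep_progressors(self):
        cfg = CohortConfig(
            n_subjects=400, metrics=metric_cfg(sd_slope=0.5, sd_resid=0.01,
                                               slope_loading=1.0),
            retention=(1.0, 0.5, 0.5, 0.5), seed=3,
            informative_dropout=2.0)
        t, truths = simulate_metric_table(cfg, return_truths=True)
        dropped = [tr.progression for tr in truths if tr.dropout_visit < 4]
        stayed = [tr.progression for tr in truths if tr.dropout_visit == 4]
        assert np.mean(dropped) > np.mean(stayed)

    @pytest.mark.parametrize("bad", [
        dict(visit_times=(1.0, 2.0)),            # must start at 0
        dict(visit_times=(0.0, 2.0, 1.0)),       # must increase
        dict(retention=(0.5, 1.0, 1.0, 1.0)),    # must be non-increasing
        dict(time_jitter=-0.1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=5, metrics=metric_cfg(), seed=0, **bad)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            MetricTruth(beta0=np.nan, beta1=0.0)
        with pytest.raises(ValueError):
            MetricTruth(beta0=1.0, beta1=0.0, sd_slope=-1.0)


class TestPhantom:
    def test_zero_drift_distributions_stable(self, static_phantom_spec):
        """With all drifts zero the NAWM MD law is visit-independent
        (two-sample Kolmogorov-Smirnov at large n)."""
        from dtiprog.histogram import build_masks, extract_values

        samples = []
        for visit in (0, 3):
            maps, probs = simulate_phantom_visit(static_phantom_spec, None,
                                                 visit, seed=5)
            masks = build_masks(probs, maps["MD"].data)
            samples.append(extract_values(masks.nawm, maps["MD"]))
        assert stats.ks_2samp(*samples).pvalue > 0.01

    def test_md_drift_raises_wm_median(self, small_phantom_spec):
        medians = []
        for visit in (0, 3):
            maps, probs = simulate_phantom_visit(small_phantom_spec, None,
                                                 visit, seed=6)
            nawm = probs["NAWM"] > 0.5
            medians.append(np.median(maps["MD"].data[nawm]))
        assert medians[1] > medians[0]

    def test_csf_md_above_filter_threshold(self, small_phantom_spec):
        maps, probs = simulate_phantom_visit(small_phantom_spec, None, 0, seed=7)
        csf_md = maps["MD"].data[probs["CSF"] > 0.5]
        assert np.median(csf_md) > 0.0026

    def test_md_consistency_and_probability_bound(self, small_phantom_spec):
        maps, probs = simulate_phantom_visit(small_phantom_spec, None, 2, seed=8)
        inside = ~np.isnan(maps["MD"].data)
        md = maps["MD"].data[inside]
        ad = maps["AD"].data[inside]
        rd = maps["RD"].data[inside]
        np.testing.assert_allclose(md, (ad + 2 * rd) / 3, rtol=1e-12)
        total = sum(probs.values())
        assert (total <= 1 + 1e-6).all()

    def test_wmh_volume_grows_with_visits(self, small_phantom_spec):
        vols = []
        for visit in range(4):
            _, probs = simulate_phantom_visit(small_phantom_spec, None, visit,
                                              seed=9)
            vols.append(probs["WMH"].sum())
        assert vols[0] > 0
        assert all(b >= a for a, b in zip(vols, vols[1:]))

    def test_same_seed_bit_identical(self, small_phantom_spec):
        a, _ = simulate_phantom_visit(small_phantom_spec, None, 1, seed=10)
        b, _ = simulate_phantom_visit(small_phantom_spec, None, 1, seed=10)
        np.testing.assert_array_equal(a["FA"].data, b["FA"].data)

    def test_too_small_lattice_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            PhantomSpec(shape=(8, 8, 8))

    def test_eigenvalue_construction_matches_fa(self):
        fa = np.array([0.0, 0.3, 0.7])
        md = np.full(3, 8e-4)
        l1, l2, l3 = eigenvalues_from_fa_md(fa, md)
        np.testing.assert_allclose((l1 + l2 + l3) / 3, md, rtol=1e-14)
        mean = (l1 + l2 + l3) / 3
        num = (l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2
        den = l1**2 + l2**2 + l3**2
        np.testing.assert_allclose(np.sqrt(1.5 * num / den), fa, atol=1e-12)


class TestDwi:
    def test_isotropic_zero_noise_intensities(self):
        d = 7e-4
        field = TensorField(np.tile([d, d, d, 0, 0, 0], (2, 2, 2, 1)))
        bvals, bvecs = gradient_scheme()
        dwi = simulate_dwi(field, bvals, bvecs, s0=800.0)
        np.testing.assert_allclose(dwi[..., bvals == 0], 800.0)
        np.testing.assert_allclose(dwi[..., bvals > 0],
                                   800.0 * np.exp(-1000.0 * d), rtol=1e-12)

    def test_scheme_shape_and_polarity(self):
        bvals, bvecs = gradient_scheme()
        assert bvals.size == 8 + 50
        assert (bvals[:8] == 0).all()
        dw = bvecs[8:]
        np.testing.assert_allclose(dw[0::2], -dw[1::2], atol=1e-14)
        np.testing.assert_allclose(np.linalg.norm(dw, axis=1), 1.0, rtol=1e-12)

    def test_rician_noise_reproducible_and_biased_up_at_low_snr(self):
        field = TensorField(np.tile([3e-3, 3e-3, 3e-3, 0, 0, 0], (6, 6, 6, 1)))
        bvals, bvecs = gradient_scheme(n_b0=1)
        a = simulate_dwi(field, bvals, bvecs, s0=100.0, noise_sd=50.0, seed=1)
        b = simulate_dwi(field, bvals, bvecs, s0=100.0, noise_sd=50.0, seed=1)
        np.testing.assert_array_equal(a, b)
        clean = simulate_dwi(field, bvals, bvecs, s0=100.0)
        # Rician floor: magnitude noise inflates weak signals
        assert a[..., bvals > 0].mean() > clean[..., bvals > 0].mean()

    def test_non_unit_gradient_rejected(self):
        field = TensorField(np.zeros((1, 6)))
        bvals = np.array([1000.0])
        with pytest.raises(ValueError, match="unit"):
            simulate_dwi(field, bvals, np.array([[2.0, 0.0, 0.0]]))

    def test_negative_b_rejected(self):
        field = TensorField(np.zeros((1, 6)))
        with pytest.raises(ValueError, match="negative"):
            simulate_dwi(field, np.array([-10.0]), np.array([[1.0, 0, 0]]))


def test_default_retention_matches_available_scans():
    assert [round(r * 99) for r in DEFAULT_RETENTION] == [99, 96, 74, 68]
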