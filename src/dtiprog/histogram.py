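"""Tissue masks, normalized histograms and the five summary metrics.

The whole longitudinal analysis runs on five numbers per tissue class and
DTI measure: the median, the histogram peak value and peak height, the
moment skewness and the excess kurtosis.  Histograms use 1000 bins over a
fixed range per measure (FA: 0-1, bin width 0.001; diffusivities:
0-0.004 mm^2 s^-1, bin width 4e-6) and are normalized to sum to one.

Masking rules: a voxel belongs to a tissue class iff its class
probability exceeds 0.5 (ties at exactly 0.5 are excluded); voxels with
MD > 0.0026 mm^2 s^-1 are then treated as contaminated by CSF and removed
from the GM/NAWM/WMH masks (the CSF mask itself is untouched).  All_WM is
the union of NAWM and WMH.

Median, skew and kurtosis are computed from the raw in-range voxel values
rather than the binned frequencies (exact and bin-free); peak value and
peak height are necessarily histogram-based.  Values outside the
histogram range are excluded from all five metrics and reported in the
``n_excluded`` count, so every metric describes the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "HistogramSpec",
    "NormalizedHistogram",
    "HistogramSummary",
    "TissueMaskSet",
    "FA_SPEC",
    "DIFFUSIVITY_SPEC",
    "spec_for",
    "build_masks",
    "extract_values",
    "normalized_histogram",
    "summarize",
    "EmptyTissueClassError",
]

#: MD above this (mm^2 s^-1) marks a voxel as CSF-contaminated
CSF_MD_THRESHOLD = 0.0026

TISSUE_CLASSES = ("GM", "NAWM", "WMH", "CSF", "lacune")
DERIVED_CLASSES = ("NAWM", "All_WM", "WMH", "CSF")


class EmptyTissueClassError(ValueError):
    """Raised when a mask selects no voxels / a value list is empty."""


@dataclass(frozen=True)
class HistogramSpec:
    """Fixed-range, fixed-bin-count histogram definition for one measure."""

    measure: str
    lower: float
    upper: float
    n_bins: int = 1000

    def __post_init__(self) -> None:
        if not (self.upper > self.lower and self.n_bins >= 1):
            raise ValueError("invalid histogram spec")

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2.0


FA_SPEC = HistogramSpec("FA", 0.0, 1.0, 1000)
DIFFUSIVITY_SPEC = HistogramSpec("MD", 0.0, 0.004, 1000)


def spec_for(measure: str) -> HistogramSpec:
    """The standard histogram spec for a measure (FA or a diffusivity)."""
    if measure == "FA":
        return FA_SPEC
    if measure in {"MD", "RD", "AD"}:
        return HistogramSpec(measure, 0.0, 0.004, 1000)
    raise ValueError(f"unknown measure {measure!r}")


@dataclass
class NormalizedHistogram:
    edges: np.ndarray
    frequencies: np.ndarray
    n_in_range: int
    n_excluded: int  # values outside [lower, upper]

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass
class HistogramSummary:
    """The five per-tissue, per-measure metrics plus bookkeeping."""

    median: float
    peak_value: float
    peak_height: float
    skew: float
    kurtosis: float
    n_voxels: int
    n_excluded: int = 0
    degenerate: bool = False  # zero variance: skew/kurtosis undefined

    def as_dict(self) -> dict[str, float]:
        return {
            "median": self.median,
            "peak_value": self.peak_value,
            "peak_height": self.peak_height,
            "skew": self.skew,
            "kurtosis": self.kurtosis,
        }


@dataclass
class TissueMaskSet:
    """Binary voxel masks per tissue class; base classes are disjoint."""

    gm: np.ndarray
    nawm: np.ndarray
    wmh: np.ndarray
    csf: np.ndarray
    lacune: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lacune is None:
            self.lacune = np.zeros_like(self.gm)
        masks = [self.gm, self.nawm, self.wmh, self.csf, self.lacune]
        shapes = {m.shape for m in masks}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        overlap = sum(m.astype(int) for m in masks)
        if (overlap > 1).any():
            raise ValueError("base tissue classes must be pairwise disjoint")

    @property
    def all_wm(self) -> np.ndarray:
        return self.nawm | self.wmh

    def __getitem__(self, tissue: str) -> np.ndarray:
        key = tissue.lower()
        if key == "all_wm":
            return self.all_wm
        if key in {"gm", "nawm", "wmh", "csf", "lacune"}:
            return getattr(self, key)
        raise KeyError(tissue)


def build_masks(
    prob_maps: Mapping[str, np.ndarray],
    md: np.ndarray,
    *,
    csf_md_threshold: float = CSF_MD_THRESHOLD,
) -> TissueMaskSet:
    """Threshold tissue probability maps and apply the CSF MD filter.

    Parameters
    ----------
    prob_maps
        Probability volumes keyed by tissue name; ``GM``, ``NAWM``,
        ``WMH`` and ``CSF`` are required, ``lacune`` optional.  Values
        must lie in [0, 1].
    md
        Co-registered MD volume (mm^2 s^-1), used to strip
        CSF-contaminated voxels out of the parenchymal masks.
    """
    md = np.asarray(md, dtype=float)
    masks: dict[str, np.ndarray] = {}
    for name in TISSUE_CLASSES:
        if name == "lacune" and name not in prob_maps:
            masks[name] = np.zeros(md.shape, dtype=bool)
            continue
        p = np.asarray(prob_maps[name], dtype=float)
        if p.shape != md.shape:
            raise ValueError(f"{name} probability map shape {p.shape} "
                             f"!= MD shape {md.shape}")
        if (p < 0).any() or (p > 1).any():
            raise ValueError(f"{name} probabilities outside [0, 1]")
        masks[name] = p > 0.5  # strict: ties at 0.5 excluded

    not_csf_like = ~(md > csf_md_threshold)
    for name in ("GM", "NAWM", "WMH"):
        masks[name] &= not_csf_like
    return TissueMaskSet(
        gm=masks["GM"], nawm=masks["NAWM"], wmh=masks["WMH"],
        csf=masks["CSF"], lacune=masks["lacune"],
    )


def extract_values(mask: np.ndarray, volume: np.ndarray | object) -> np.ndarray:
    """Values at mask-true voxels, as a flat array.

    Accepts a bare array or anything with a ``.data`` array attribute
    (e.g. :class:`~dtiprog.tensor.ScalarVolume`).
    """
    data = getattr(volume, "data", volume)
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {data.shape}")
    if not mask.any():
        raise EmptyTissueClassError("empty tissue class")
    return data[mask]


def _in_range(values: np.ndarray, spec: HistogramSpec) -> tuple[np.ndarray, int]:
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    keep = (values >= spec.lower) & (values <= spec.upper)
    return values[keep], int((~keep).sum())


def normalized_histogram(values: np.ndarray, spec: HistogramSpec) -> NormalizedHistogram:
    """Counts over ``n_bins`` half-open bins (last bin closed), divided by
    the number of in-range values."""
    inside, n_excl = _in_range(values, spec)
    if inside.size == 0:
        raise EmptyTissueClassError("no values inside the histogram range")
    counts, edges = np.histogram(inside, bins=spec.n_bins,
                                 range=(spec.lower, spec.upper))
    return NormalizedHistogram(
        edges=edges,
        frequencies=counts / inside.size,
        n_in_range=int(inside.size),
        n_excluded=n_excl,
    )


def summarize(values: np.ndarray, spec: HistogramSpec) -> HistogramSummary:
    """The five histogram metrics for one tissue class and measure.

    Median, skew (m3 / m2^1.5) and excess kurtosis (m4 / m2^2 - 3) are
    moment statistics of the raw in-range values; peak value and height
    come from the normalized histogram, ties broken toward the lowest bin
    and the peak location reported as that bin's center.
    """
    hist = normalized_histogram(values, spec)
    inside, _ = _in_range(values, spec)

    peak_bin = int(np.argmax(hist.frequencies))  # argmax takes the first max
    peak_height = float(hist.frequencies[peak_bin])
    peak_value = float(hist.centers[peak_bin])

    median = float(np.median(inside))
    degenerate = bool(inside.size < 2 or np.all(inside == inside[0]))
    if degenerate:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(inside, bias=True))
        kurt = float(stats.kurtosis(inside, fisher=True, bias=True))
    return HistogramSummary(
        median=median,
        peak_value=peak_value,
        peak_height=peak_height,
        skew=skew,
        kurtosis=kurt,
        n_voxels=hist.n_in_range,
        n_excluded=hist.n_excluded,
        degenerate=degenerate,
    )
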