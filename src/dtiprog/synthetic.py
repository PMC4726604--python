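"""Synthetic longitudinal cohorts for small-vessel-disease DTI studies.

Two generation paths, both fully seeded:

* :func:`simulate_metric_table` draws per-visit histogram-metric values
  directly from a known linear mixed-effects law — fixed intercept and
  slope, bivariate-Gaussian random intercept/slope per subject, i.i.d.
  Gaussian residual — with visit-time jitter and (by default
  completely-at-random) monotone dropout.  This is the workhorse for
  testing the model-fitting, power and PCA stages against known truth.

* :func:`simulate_phantom_visit` builds voxel-level FA/MD/RD/AD volumes on
  a small lattice with a simple tissue geometry (brain ellipsoid, GM
  shell, WM interior, ventricular CSF, growing periventricular WMH blobs,
  a few lacunes) whose per-tissue value distributions drift over visits
  the way a progressing small vessel disease cohort's do: WM anisotropy
  falls, WM diffusivity rises and broadens, CSF stays put.  RD and AD are
  constructed from an axially symmetric tensor so MD = (AD + 2 RD) / 3
  holds exactly at every voxel.  :func:`simulate_dwi` turns a tensor
  field into a diffusion-weighted stack (8 b0 volumes plus 25 directions
  and their negatives at b = 1000 s mm^-2) with Rician noise, for
  exercising the tensor-fitting path end to end.

The default cohort shape mirrors a 99-subject study scanned at ~0/1/2/3
years with 99/96/74/68 usable scans per visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tensor import ScalarVolume, TensorField

__all__ = [
    "MetricTruth",
    "CohortConfig",
    "SubjectTruth",
    "TissueDistribution",
    "PhantomSpec",
    "DEFAULT_RETENTION",
    "simulate_metric_table",
    "draw_subject_truths",
    "simulate_phantom_visit",
    "phantom_labels",
    "gradient_scheme",
    "simulate_dwi",
    "eigenvalues_from_fa_md",
]

#: per-visit retention fractions matching 99/96/74/68 usable scans of 99
DEFAULT_RETENTION = (1.0, 96 / 99, 74 / 99, 68 / 99)


@dataclass(frozen=True)
class MetricTruth:
    """True mixed-model parameters for one metric.

    ``intercept_loading`` / ``slope_loading`` couple this metric's random
    effects to cohort-wide latent severity factors (one for baselines,
    one for progression rates), producing the cross-metric correlation
    real DTI metrics show; the loading is the correlation with the latent
    factor and the remainder of the random-effect variance is unique.
    """

    beta0: float
    beta1: float
    sd_intercept: float = 0.0
    sd_slope: float = 0.0
    corr: float = 0.0          # intercept-slope correlation within metric
    sd_resid: float = 0.0
    intercept_loading: float = 0.0
    slope_loading: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.beta0, self.beta1, self.sd_intercept, self.sd_slope,
                self.corr, self.sd_resid)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite metric truth parameter")
        if min(self.sd_intercept, self.sd_slope, self.sd_resid) < 0:
            raise ValueError("standard deviations must be >= 0")
        for r in (self.corr, self.intercept_loading, self.slope_loading):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations/loadings must lie in [-1, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, schedule, dropout and per-metric truth."""

    n_subjects: int
    metrics: Mapping[str, MetricTruth]
    visit_times: Sequence[float] = (0.0, 1.0, 2.0, 3.0)
    retention: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0
    time_jitter: float = 0.1   # uniform +-jitter (years) on follow-up visits
    #: 0 = missing completely at random; >0 tilts dropout toward subjects
    #: with steeper latent progression (more vulnerable patients leave)
    informative_dropout: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.visit_times, dtype=float)
        if t.size == 0:
            raise ValueError("empty visit schedule")
        if t[0] != 0 or (np.diff(t) <= 0).any():
            raise ValueError("visit times must be strictly increasing from 0")
        r = np.asarray(self.retention, dtype=float)
        if r.size != t.size:
            raise ValueError("retention must match the visit schedule")
        if (np.diff(r) > 1e-12).any() or (r < 0).any() or (r > 1).any():
            raise ValueError("retention fractions must be non-increasing in [0,1]")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not self.metrics:
            raise ValueError("no metrics configured")
        if self.time_jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class SubjectTruth:
    """Realized per-subject parameters (bookkeeping for tests/phantoms)."""

    subject_id: int
    intercepts: dict[str, float]
    slopes: dict[str, float]
    dropout_visit: int  # index of first missed visit; == n_visits if none
    severity: float = 0.0       # latent baseline-severity factor
    progression: float = 0.0    # latent progression factor


def _retained_counts(n: int, retention: Sequence[float]) -> np.ndarray:
    counts = np.rint(np.asarray(retention, dtype=float) * n).astype(int)
    return np.minimum.accumulate(np.clip(counts, 0, n))


def draw_subject_truths(config: CohortConfig,
                        rng: np.random.Generator) -> list[SubjectTruth]:
    """Draw the per-subject random effects and dropout visits."""
    n = config.n_subjects
    sev = rng.standard_normal(n)
    prog = rng.standard_normal(n)
    intercepts: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    for name, tr in config.metrics.items():
        # intercept: latent share + unique share; slope additionally
        # correlated with the metric's own intercept via tr.corr
        li, ls = tr.intercept_loading, tr.slope_loading
        z0 = li * sev + math.sqrt(max(1 - li * li, 0.0)) * rng.standard_normal(n)
        resid = math.sqrt(max(1 - tr.corr**2 - ls * ls, 0.0))
        z1 = tr.corr * z0 + ls * prog + resid * rng.standard_normal(n)
        intercepts[name] = tr.beta0 + tr.sd_intercept * z0
        slopes[name] = tr.beta1 + tr.sd_slope * z1

    counts = _retained_counts(n, config.retention)
    n_visits = len(config.visit_times)
    dropout = np.full(n, n_visits, dtype=int)
    active = np.arange(n)
    for v in range(1, n_visits):
        n_drop = active.size - counts[v]
        if n_drop > 0:
            if config.informative_dropout > 0:
                w = np.exp(config.informative_dropout * prog[active])
                w /= w.sum()
            else:
                w = None
            drop = rng.choice(active, size=n_drop, replace=False, p=w)
            dropout[drop] = v
            active = np.setdiff1d(active, drop)
    return [
        SubjectTruth(
            subject_id=i,
            intercepts={k: float(v[i]) for k, v in intercepts.items()},
            slopes={k: float(v[i]) for k, v in slopes.items()},
            dropout_visit=int(dropout[i]),
            severity=float(sev[i]),
            progression=float(prog[i]),
        )
        for i in range(n)
    ]


def simulate_metric_table(
    config: CohortConfig,
    *,
    return_truths: bool = False,
):
    """Long-format cohort table of per-visit metric values.

    Columns: ``subject_id``, ``visit``, ``time_years``, ``metric``,
    ``value``.  Values follow
    ``beta0 + u0_i + (beta1 + u1_i) * t + e`` with the configured
    bivariate random-effect law; follow-up times are jittered uniformly
    within +-``time_jitter`` years (baseline stays exactly 0); rows are
    removed according to the monotone dropout schedule.
    """
    rng = np.random.default_rng(config.seed)
    truths = draw_subject_truths(config, rng)
    sched = np.asarray(config.visit_times, dtype=float)
    rows = []
    for tr in truths:
        n_vis = tr.dropout_visit
        times = sched[:n_vis].copy()
        if config.time_jitter > 0 and n_vis > 1:
            times[1:] += rng.uniform(-config.time_jitter,
                                     config.time_jitter, n_vis - 1)
        for name, truth in config.metrics.items():
            eps = rng.normal(0.0, truth.sd_resid, n_vis)
            vals = (tr.intercepts[name]
                    + tr.slopes[name] * times + eps)
            for v in range(n_vis):
                rows.append((tr.subject_id, v, times[v], name, vals[v]))
    table = pd.DataFrame(
        rows, columns=["subject_id", "visit", "time_years", "metric", "value"]
    )
    if return_truths:
        return table, truths
    return table


# ---------------------------------------------------------------------------
# voxel-level phantom


@dataclass(frozen=True)
class TissueDistribution:
    """Gaussian FA/MD value law for one tissue class, with annual drift.

    Locations/scales in FA units and mm^2 s^-1; ``md_scale_drift``
    broadens the MD distribution over time (what lowers the histogram
    peak height in progressing white matter).
    """

    fa_loc: float
    fa_scale: float
    md_loc: float
    md_scale: float
    fa_drift: float = 0.0        # FA location change per year
    md_drift: float = 0.0        # MD location change per year (mm^2/s/yr)
    md_scale_drift: float = 0.0  # MD scale change per year


#: per-tissue defaults emulating a progressing SVD cohort: WM FA falls,
#: WM diffusivity rises and broadens, WMH worse than NAWM, CSF static
SVD_TISSUES: dict[str, TissueDistribution] = {
    "GM": TissueDistribution(0.15, 0.05, 0.95e-3, 0.12e-3,
                             -0.001, 2e-6, 0.0),
    "NAWM": TissueDistribution(0.32, 0.09, 0.80e-3, 0.09e-3,
                               -0.008, 8e-6, 6e-6),
    "WMH": TissueDistribution(0.24, 0.08, 1.15e-3, 0.15e-3,
                              -0.006, 12e-6, 8e-6),
    "CSF": TissueDistribution(0.06, 0.03, 3.0e-3, 0.25e-3,
                              0.0, 0.0, 0.0),
    "lacune": TissueDistribution(0.08, 0.03, 2.8e-3, 0.25e-3,
                                 0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and value laws for the voxel-level phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    brain_axes_frac: tuple[float, float, float] = (0.92, 0.92, 0.88)
    gm_shell_frac: float = 0.78      # inside this fraction -> white matter
    ventricle_axes_frac: tuple[float, float, float] = (0.16, 0.30, 0.16)
    n_wmh_blobs: int = 4
    wmh_base_radius_vox: float = 2.5
    wmh_growth_per_visit: float = 1.15  # radius multiplier per visit
    n_lacunes: int = 3
    lacune_radius_vox: float = 1.2
    tissues: Mapping[str, TissueDistribution] = field(
        default_factory=lambda: dict(SVD_TISSUES))

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("lattice too small to contain the tissue regions")
        if self.wmh_growth_per_visit < 1.0:
            raise ValueError("WMH growth factor must be >= 1")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def phantom_labels(spec: PhantomSpec, visit_index: int = 0,
                   seed: int = 0) -> np.ndarray:
    """Integer label volume: 0 background, 1 GM, 2 NAWM, 3 WMH, 4 CSF,
    5 lacune.  WMH blobs grow with ``visit_index``; the rest is static.
    Blob and lacune placement is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    shape = spec.shape
    center = tuple((s - 1) / 2 for s in shape)
    half = tuple(s / 2 for s in shape)
    brain = _ellipsoid(shape, center,
                       [h * f for h, f in zip(half, spec.brain_axes_frac)])
    inner = _ellipsoid(shape, center,
                       [h * f * spec.gm_shell_frac
                        for h, f in zip(half, spec.brain_axes_frac)])
    vent = _ellipsoid(shape, center,
                      [h * f for h, f in zip(half, spec.ventricle_axes_frac)])

    labels = np.zeros(shape, dtype=np.uint8)
    labels[brain] = 1                    # GM shell
    labels[inner] = 2                    # white matter interior
    labels[vent & inner] = 4             # ventricular CSF

    # periventricular WMH blobs on a ring just outside the ventricles
    vent_r = max(h * f for h, f in zip(half, spec.ventricle_axes_frac))
    for _ in range(spec.n_wmh_blobs):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dist = vent_r + 2.0 + rng.uniform(0, 2.0)
        c = np.asarray(center) + direction * dist
        r = spec.wmh_base_radius_vox * spec.wmh_growth_per_visit ** visit_index
        blob = _ellipsoid(shape, c, (r, r, r))
        labels[blob & (labels == 2)] = 3

    for _ in range(spec.n_lacunes):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dist = vent_r + 4.0 + rng.uniform(0, 4.0)
        c = np.asarray(center) + direction * dist
        lac = _ellipsoid(shape, c,
                         (spec.lacune_radius_vox,) * 3)
        labels[lac & ((labels == 2) | (labels == 3))] = 5
    return labels


def eigenvalues_from_fa_md(fa: np.ndarray, md: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axially symmetric eigenvalues (l1, l2, l3=l2) with the given FA
    and MD; MD = (l1 + 2 l2) / 3 holds exactly.

    For a prolate tensor l1 = MD (1 + 2 d), l2 = l3 = MD (1 - d) with
    d = FA * sqrt(3 / (9 - 6 FA^2)); FA must be < sqrt(3/2) * ... < 1
    for d < 1 (non-negative radial eigenvalue), which holds on [0, 1).
    """
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    d = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    l1 = md * (1 + 2 * d)
    l2 = md * (1 - d)
    return l1, l2, l2.copy()


_LABEL_NAMES = {1: "GM", 2: "NAWM", 3: "WMH", 4: "CSF", 5: "lacune"}


def simulate_phantom_visit(
    spec: PhantomSpec,
    truth: SubjectTruth | None,
    visit_index: int,
    *,
    seed: int = 0,
    visit_years: float | None = None,
) -> tuple[dict[str, ScalarVolume], dict[str, np.ndarray]]:
    """One subject-visit's FA/MD/RD/AD volumes plus probability maps.

    Voxel values are drawn from the tissue distributions shifted by the
    per-year drifts (``visit_years`` defaults to ``visit_index``, i.e.
    annual visits).  ``truth`` may carry per-tissue offsets in its
    ``intercepts``/``slopes`` dicts keyed ``"<tissue>:FA"`` /
    ``"<tissue>:MD"``; pass None for a population-average subject.
    Probability maps are noiseless indicators of the label geometry and
    therefore sum to 1 inside the head and 0 outside.
    """
    t = float(visit_index if visit_years is None else visit_years)
    subject_id = truth.subject_id if truth is not None else 0
    labels = phantom_labels(spec, visit_index, seed=seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, subject_id, visit_index]))

    fa = np.zeros(spec.shape)
    md = np.zeros(spec.shape)
    for lab, name in _LABEL_NAMES.items():
        m = labels == lab
        if not m.any():
            continue
        dist = spec.tissues[name]
        fa_loc = dist.fa_loc + dist.fa_drift * t
        md_loc = dist.md_loc + dist.md_drift * t
        md_scale = dist.md_scale + dist.md_scale_drift * t
        if truth is not None:
            fa_loc += truth.intercepts.get(f"{name}:FA", 0.0) \
                + truth.slopes.get(f"{name}:FA", 0.0) * t
            md_loc += truth.intercepts.get(f"{name}:MD", 0.0) \
                + truth.slopes.get(f"{name}:MD", 0.0) * t
        n = int(m.sum())
        fa[m] = np.clip(rng.normal(fa_loc, dist.fa_scale, n), 0.01, 0.95)
        md[m] = np.clip(rng.normal(md_loc, md_scale, n), 1e-5, 3.9e-3)

    inside = labels > 0
    l1, l2, _ = eigenvalues_from_fa_md(fa, md)
    ad = np.where(inside, l1, np.nan)
    rd = np.where(inside, l2, np.nan)
    fa_v = np.where(inside, fa, np.nan)
    md_v = np.where(inside, md, np.nan)

    maps = {
        "FA": ScalarVolume(fa_v, "FA", spec.spacing),
        "MD": ScalarVolume(md_v, "MD", spec.spacing),
        "RD": ScalarVolume(rd, "RD", spec.spacing),
        "AD": ScalarVolume(ad, "AD", spec.spacing),
    }
    probs = {name: (labels == lab).astype(np.float32)
             for lab, name in _LABEL_NAMES.items()}
    return maps, probs


# ---------------------------------------------------------------------------
# diffusion-weighted signal


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + math.sqrt(5)) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def gradient_scheme(
    n_directions: int = 25, n_b0: int = 8, b: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """b-values and unit gradients: ``n_b0`` null volumes followed by
    each direction and its negative stored adjacently.

    Returns ``(bvals (N,), bvecs (N, 3))`` with
    ``N = n_b0 + 2 * n_directions``.
    """
    dirs = _sphere_directions(n_directions)
    bvecs = [np.zeros((n_b0, 3))]
    for d in dirs:
        bvecs.append(d[None, :])
        bvecs.append(-d[None, :])
    bvecs = np.concatenate(bvecs, axis=0)
    bvals = np.concatenate([np.zeros(n_b0),
                            np.full(2 * n_directions, float(b))])
    return bvals, bvecs


def simulate_dwi(
    tensors: TensorField,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    *,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Diffusion-weighted stack S = S0 exp(-b g' D g) with Rician noise.

    Rician noise adds independent Gaussians to the real and imaginary
    channels: S_noisy = sqrt((S + n1)^2 + n2^2).  The default
    ``noise_sd=0`` returns the clean magnitude signal.  Output shape is
    ``tensors.shape + (N,)`` with the volumes in scheme order.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, bvals.size) and bvals.size != 3:
        bvecs = bvecs.T
    if (bvals < 0).any():
        raise ValueError("negative b-value")
    norms = np.linalg.norm(bvecs, axis=1)
    if not np.allclose(norms[bvals > 0], 1.0, atol=1e-6):
        raise ValueError("gradient directions must be unit vectors")

    D = tensors.as_matrices()  # (..., 3, 3)
    # quadratic form g' D g for every voxel and direction
    q = np.einsum("...ij,nj,ni->...n", D, bvecs, bvecs)
    signal = s0 * np.exp(-bvals * q)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sd, signal.shape)
        n2 = rng.normal(0.0, noise_sd, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return signal
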