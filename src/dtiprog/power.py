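"""Sample-size estimation for slope-difference trials, with a
Monte-Carlo power oracle.

The trial is a hypothetical 3-year, two-arm, balanced design with annual
measurements (t = 0, 1, 2, 3 years by default).  A treatment effect of
e% means the treated arm's mean slope is reduced proportionally,
Delta = (e / 100) * |beta1|, with variance components unchanged.  The
per-subject variance of an individual OLS slope estimate under the
random-intercept/slope model is

    V = sigma_b1^2 + sigma_e^2 / sum_j (t_j - tbar)^2

and the per-arm sample size for two-sided level alpha and target power is
the slope-difference formula

    n = 2 (z_{1-alpha/2} + z_{power})^2 * V / Delta^2

rounded up to an integer.  ``mc_power`` verifies the formula by
simulating full trials and refitting the group/time/group-by-time mixed
model per replicate, rejecting on the interaction's Wald test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._fastlme import Stratum, fit_profiled_ml
from .lme import LmeFit

__all__ = [
    "TrialDesign",
    "SampleSizeEstimate",
    "PowerResult",
    "slope_variance",
    "sample_size",
    "sample_size_table",
    "mc_power",
]


@dataclass(frozen=True)
class TrialDesign:
    visit_times: Sequence[float] = (0.0, 1.0, 2.0, 3.0)
    alpha: float = 0.05           # two-sided
    power: float = 0.80
    effects_pct: Sequence[float] = (30.0, 25.0, 20.0, 15.0)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        t = np.asarray(self.visit_times, dtype=float)
        if t.size < 2 or np.ptp(t) == 0:
            raise ValueError("need >=2 distinct visit times")

    @property
    def sxx(self) -> float:
        t = np.asarray(self.visit_times, dtype=float)
        return float(((t - t.mean()) ** 2).sum())


@dataclass
class SampleSizeEstimate:
    effect_pct: float
    delta: float          # absolute slope difference, units / year
    slope_variance: float
    n_continuous: float
    n_per_arm: int


@dataclass
class PowerResult:
    power: float
    n_rejections: int
    n_converged: int
    n_replicates: int

    @property
    def mc_se(self) -> float:
        p = self.power
        return math.sqrt(p * (1 - p) / self.n_converged)


def slope_variance(fit: LmeFit, design: TrialDesign) -> float:
    """Variance of a single subject's estimated slope under the design.

    V = var(random slope) + residual variance / Sxx, with Sxx the spread
    of the visit times (Sxx = 5 for t = 0..3).
    """
    sxx = design.sxx
    if sxx == 0:
        raise ValueError("degenerate visit schedule")
    return fit.var_b1 + fit.sigma2_e / sxx


def sample_size(
    fit: LmeFit, design: TrialDesign, effect_pct: float
) -> SampleSizeEstimate:
    """Minimum per-arm n to detect a proportional slope reduction."""
    if effect_pct <= 0:
        raise ValueError("effect percentage must be > 0")
    if fit.beta1 == 0:
        raise ZeroDivisionError(
            "zero progression slope: required sample size is infinite")
    delta = abs(fit.beta1) * effect_pct / 100.0
    V = slope_variance(fit, design)
    z = norm.ppf(1 - design.alpha / 2) + norm.ppf(design.power)
    n_cont = 2.0 * z**2 * V / delta**2
    return SampleSizeEstimate(
        effect_pct=float(effect_pct),
        delta=delta,
        slope_variance=V,
        n_continuous=n_cont,
        n_per_arm=int(math.ceil(n_cont)),
    )


def sample_size_table(
    fits: "dict[str, LmeFit]", design: TrialDesign | None = None
) -> pd.DataFrame:
    """Per-arm sample sizes for every metric over the effect grid."""
    design = design or TrialDesign()
    rows = []
    for name, fit in fits.items():
        row: dict[str, object] = {"metric": name}
        for e in design.effects_pct:
            row[f"n_{e:g}pct"] = sample_size(fit, design, e).n_per_arm
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_trial(
    rng: np.random.Generator,
    times: np.ndarray,
    n_per_arm: int,
    beta0: float,
    slope_ctrl: float,
    slope_trt: float,
    sd_intercept: float,
    sd_slope: float,
    corr: float,
    sd_resid: float,
    keep: "list[np.ndarray] | None",
) -> list[Stratum]:
    m = times.size
    cov = np.array([
        [sd_intercept**2, corr * sd_intercept * sd_slope],
        [corr * sd_intercept * sd_slope, sd_slope**2],
    ])
    chol = np.linalg.cholesky(cov) if (sd_intercept or sd_slope) else np.zeros((2, 2))
    strata: list[Stratum] = []
    for arm, slope in ((0, slope_ctrl), (1, slope_trt)):
        re = rng.standard_normal((n_per_arm, 2)) @ chol.T
        b0 = beta0 + re[:, 0]
        b1 = slope + re[:, 1]
        Y = b0[:, None] + b1[:, None] * times[None, :] \
            + rng.normal(0.0, sd_resid, (n_per_arm, m))
        if keep is None:
            X = np.column_stack([np.ones(m), np.full(m, arm),
                                 times, arm * times])
            strata.append(Stratum.from_responses(times, X, Y))
        else:
            # dropout: group subjects by retained-visit count (monotone)
            n_kept = keep[arm]
            for k in np.unique(n_kept):
                sel = n_kept == k
                tk = times[:k]
                X = np.column_stack([np.ones(k), np.full(k, arm),
                                     tk, arm * tk])
                strata.append(Stratum.from_responses(tk, X, Y[sel, :k]))
    return strata


def mc_power(
    design: TrialDesign,
    *,
    beta0: float = 0.0,
    beta1: float,
    effect_pct: float,
    n_per_arm: int,
    sd_intercept: float = 0.0,
    sd_slope: float = 0.0,
    corr: float = 0.0,
    sd_resid: float = 1.0,
    reps: int = 2000,
    seed: int = 0,
    retention: Sequence[float] | None = None,
    reml: bool = True,
) -> PowerResult:
    """Empirical power of the treatment-by-time Wald test.

    Each replicate simulates a balanced two-arm trial (control slope
    ``beta1``, treated slope ``beta1 * (1 - effect_pct / 100)``), fits
    the LME with group, time and group-by-time fixed effects plus random
    intercept and slope, and tests the interaction at the design's
    two-sided alpha.  Variance components are estimated by REML by
    default (the conventional choice for Wald inference; full-ML Wald
    tests are mildly anticonservative at these arm sizes).
    Non-convergent replicates are excluded from the denominator and
    reported.

    ``retention`` optionally applies a monotone per-visit retention
    schedule to each arm (sensitivity analysis; the formula itself
    assumes complete follow-up).
    """
    if reps < 100:
        raise ValueError("use >=100 replicates")
    times = np.asarray(design.visit_times, dtype=float)
    slope_trt = beta1 * (1.0 - effect_pct / 100.0)
    rng = np.random.default_rng(seed)
    rej = conv = 0
    for _ in range(reps):
        if retention is not None:
            keep = []
            counts = np.rint(np.asarray(retention, dtype=float)
                             * n_per_arm).astype(int)
            counts = np.minimum.accumulate(np.clip(counts, 1, n_per_arm))
            for _arm in range(2):
                n_kept = np.full(n_per_arm, times.size, dtype=int)
                active = rng.permutation(n_per_arm)
                lost = 0
                for v in range(1, times.size):
                    drop = n_per_arm - counts[v] - lost
                    if drop > 0:
                        n_kept[active[lost:lost + drop]] = v
                        lost += drop
                keep.append(n_kept)
        else:
            keep = None
        strata = _simulate_trial(
            rng, times, n_per_arm, beta0, beta1, slope_trt,
            sd_intercept, sd_slope, corr, sd_resid, keep)
        fit = fit_profiled_ml(strata, reml=reml)
        if not fit.converged:
            continue
        conv += 1
        _, p = fit.wald(3)  # group-by-time interaction
        if p <= design.alpha:
            rej += 1
    if conv == 0:
        raise RuntimeError("no replicate converged")
    return PowerResult(
        power=rej / conv,
        n_rejections=rej,
        n_converged=conv,
        n_replicates=reps,
    )
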