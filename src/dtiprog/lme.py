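"""Linear mixed-effects trajectory fits for histogram metrics.

Each metric is modelled as a linear trend in exact time since baseline
(years), with fixed intercept and slope plus per-subject random intercept
and slope with an unstructured 2x2 covariance:

    y_it = (b0 + u0_i) + (b1 + u1_i) * t_it + e_it

Fitting is maximum likelihood through :class:`statsmodels.MixedLM`
(``reml=False``); every available observation is used, so unbalanced
follow-up and dropout are handled naturally.  The slope is tested with a
Wald chi-square on 1 df, significance is Bonferroni-corrected across the
metric family, and change rates / residual errors are also expressed as
percentages of the fitted average intercept (the average baseline value).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

__all__ = [
    "LmeFit",
    "fit_lme",
    "wald_test",
    "bonferroni",
    "truncate_sigfigs",
    "progression_report",
    "BONFERRONI_FAMILY_SIZE",
]

#: 5 histogram metrics x 4 DTI measures + 1 composite score per tissue class
BONFERRONI_FAMILY_SIZE = 21


@dataclass
class LmeFit:
    """Result of one metric's trajectory fit."""

    beta0: float           # fixed intercept (metric units)
    beta1: float           # fixed slope (units / year)
    se_beta0: float
    se_beta1: float
    var_b0: float          # random-intercept variance
    var_b1: float          # random-slope variance
    cov_b01: float
    sigma2_e: float        # residual variance
    wald_chi2: float
    p_value: float
    n_subjects: int
    n_obs: int
    loglik: float
    converged: bool
    singular: bool = False
    intercept_only: bool = False  # fallback model was used

    @property
    def sigma_e(self) -> float:
        return math.sqrt(self.sigma2_e)

    @property
    def re_correlation(self) -> float:
        d = math.sqrt(self.var_b0 * self.var_b1)
        return self.cov_b01 / d if d > 0 else 0.0


def fit_lme(
    table: pd.DataFrame,
    *,
    value_col: str = "value",
    time_col: str = "time_years",
    subject_col: str = "subject_id",
    reml: bool = False,
) -> LmeFit:
    """Fit the random-intercept/slope trajectory model for one metric.

    ``table`` holds one row per subject-visit.  On non-convergence the
    model is refit with a random intercept only and flagged.
    """
    df = table[[subject_col, time_col, value_col]].dropna()
    if df.empty:
        raise ValueError("empty metric table")
    y = df[value_col].to_numpy(dtype=float)
    t = df[time_col].to_numpy(dtype=float)
    groups = df[subject_col].to_numpy()
    X = np.column_stack([np.ones_like(t), t])

    # fit on the standardized response for numerical robustness across the
    # ~6 orders of magnitude the histogram metrics span, then map back
    # (an exact reparameterization: beta, SEs scale by s, variances by s^2)
    mu, s = float(y.mean()), float(y.std())
    if s == 0:
        s = 1.0
    ys = (y - mu) / s

    def _run(exog_re: np.ndarray) -> sm.regression.mixed_linear_model.MixedLMResults:
        # optimizer cascade: lbfgs is fastest but can stall on nearly
        # singular random-effect covariances; cg/powell then usually
        # reach the optimum.  Keep the best converged fit (or the best
        # likelihood seen if none converges).
        model = sm.MixedLM(ys, X, groups=groups, exog_re=exog_re)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "cg", "powell"):
                try:
                    res = model.fit(reml=reml, method=method, maxiter=200)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    return res
                if best is None or res.llf > best.llf:
                    best = res
        if best is None:
            raise np.linalg.LinAlgError("all optimizers failed")
        return best

    intercept_only = False
    try:
        res = _run(X)
        converged = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError):
        converged = False
        res = None
    if res is None or not converged:
        try:
            res_fallback = _run(X[:, :1])
        except (np.linalg.LinAlgError, ValueError):
            res_fallback = None
        if res is None and res_fallback is None:
            raise np.linalg.LinAlgError(
                "mixed-model fit failed for both covariance structures")
        if res_fallback is not None and (res is None
                                         or res_fallback.converged):
            res = res_fallback
            converged = bool(res.converged)
            intercept_only = True

    beta0 = mu + s * float(res.params[0])
    beta1 = s * float(res.params[1])
    se0, se1 = s * float(res.bse[0]), s * float(res.bse[1])
    cov_re = s**2 * np.asarray(res.cov_re, dtype=float)
    if intercept_only:
        var_b0, var_b1, cov_b01 = float(cov_re[0, 0]), 0.0, 0.0
    else:
        var_b0 = float(cov_re[0, 0])
        var_b1 = float(cov_re[1, 1])
        cov_b01 = float(cov_re[0, 1])
    sigma2_e = s**2 * float(res.scale)
    singular = bool(min(var_b0, var_b1 if not intercept_only else var_b0)
                    <= 1e-12 * max(sigma2_e, 1e-300))
    if se1 > 0:
        w = (beta1 / se1) ** 2
        p = float(chi2.sf(w, df=1))
    else:
        w, p = float("inf"), 0.0
    return LmeFit(
        beta0=beta0, beta1=beta1, se_beta0=se0, se_beta1=se1,
        var_b0=var_b0, var_b1=var_b1, cov_b01=cov_b01,
        sigma2_e=sigma2_e, wald_chi2=float(w), p_value=p,
        n_subjects=int(pd.unique(groups).size), n_obs=int(y.size),
        loglik=float(res.llf) - y.size * math.log(s), converged=converged,
        singular=singular, intercept_only=intercept_only,
    )


def wald_test(fit: LmeFit) -> tuple[float, float]:
    """Wald chi-square (1 df) and p-value for the fixed slope."""
    if fit.se_beta1 <= 0:
        raise ZeroDivisionError("zero slope standard error")
    w = (fit.beta1 / fit.se_beta1) ** 2
    return float(w), float(chi2.sf(w, df=1))


def truncate_sigfigs(x: float, sig: int = 2) -> float:
    """Truncate (toward zero) to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - sig + 1)
    return math.trunc(x / scale) * scale


def bonferroni(
    p_values: "list[float] | np.ndarray",
    m: int = BONFERRONI_FAMILY_SIZE,
    alpha: float = 0.05,
) -> tuple[float, float, np.ndarray]:
    """Bonferroni threshold for a family of ``m`` slope tests.

    Returns the full-precision threshold alpha/m, the threshold truncated
    to two significant figures (the conventional printed form; 0.05/21
    -> 0.0023), and per-test flags ``p <= truncated threshold``.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value list")
    if m < 1:
        raise ValueError("m must be >= 1")
    full = alpha / m
    truncated = truncate_sigfigs(full, 2)
    return full, truncated, p_values <= truncated


def progression_report(
    fits: "dict[str, LmeFit]",
    *,
    m: int = BONFERRONI_FAMILY_SIZE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate change rates, residual errors and significance per metric.

    Percentages are relative to the fitted average intercept (the average
    baseline value): % annual change = 100 * b1 / b0 and % residual
    error = 100 * sigma_e^2 / b0 (the residual variance parameter is the
    reported "residual error").
    """
    names = list(fits)
    for name in names:
        if fits[name].beta0 == 0:
            raise ZeroDivisionError(f"zero average intercept for {name}")
    _, threshold, flags = bonferroni([fits[n].p_value for n in names],
                                     m=m, alpha=alpha)
    rows = []
    for name, sig in zip(names, flags):
        f = fits[name]
        rows.append({
            "metric": name,
            "rate": f.beta1,
            "se_rate": f.se_beta1,
            "pct_annual_change": 100.0 * f.beta1 / f.beta0,
            "residual_error": f.sigma2_e,
            "pct_residual_error": 100.0 * f.sigma2_e / f.beta0,
            "chi2": f.wald_chi2,
            "p_value": f.p_value,
            "significant": bool(sig),
            "intercept": f.beta0,
            "converged": f.converged,
        })
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out
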