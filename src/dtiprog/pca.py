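"""Baseline-anchored principal-component composite of DTI metrics.

To collapse the correlated histogram metrics into a single progression
score, PCA is applied to the baseline visit only: variables are the FA
and MD metrics whose slope test survived Bonferroni correction (RD and AD
are always excluded as sub-parameters of MD that would otherwise make the
correlation matrix near-singular).  Components with eigenvalue > 1 are
retained; with more than one retained component a promax rotation
(kappa = 4) is applied.  Follow-up visits are scored with the baseline
model: values are standardized by the *baseline* means and SDs and
multiplied by the regression-method score coefficients W = R^-1 S (R the
baseline correlation matrix, S the structure matrix), so the score's
drift over visits measures progression on the baseline axis.

A correlation-matrix determinant below 1e-4 raises a multicollinearity
warning, mirroring the usual PCA diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import promax

from .lme import LmeFit, fit_lme

__all__ = [
    "PcaModel",
    "MulticollinearityWarning",
    "NoRetainedComponentError",
    "select_variables",
    "fit_pca_baseline",
    "score_visits",
    "composite_progression",
]

DETERMINANT_GUARD = 1e-4


class MulticollinearityWarning(UserWarning):
    """Correlation-matrix determinant below the collinearity guard."""


class NoRetainedComponentError(ValueError):
    """No eigenvalue exceeded 1 (e.g. uncorrelated variables)."""


@dataclass
class PcaModel:
    variables: list[str]
    means: np.ndarray            # baseline means per variable
    sds: np.ndarray              # baseline SDs per variable
    corr_determinant: float
    eigenvalues: np.ndarray      # all, descending
    n_retained: int
    loadings: np.ndarray         # (p, k) pattern matrix (promax if k > 1)
    score_coefficients: np.ndarray  # (p, k) regression-method weights
    pct_variance: float          # retained eigenvalue share, %
    collinearity_warning: bool = False
    underdetermined: bool = False  # fewer subjects than variables
    n_subjects: int = 0

    def to_dict(self) -> dict:
        """Plain-python form for YAML serialization."""
        return {
            "variables": list(self.variables),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "corr_determinant": float(self.corr_determinant),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": int(self.n_retained),
            "loadings": self.loadings.tolist(),
            "score_coefficients": self.score_coefficients.tolist(),
            "pct_variance": float(self.pct_variance),
            "collinearity_warning": bool(self.collinearity_warning),
            "n_subjects": int(self.n_subjects),
        }


def select_variables(report: pd.DataFrame) -> list[str]:
    """Metrics eligible for the composite: FA/MD only, significant slope.

    ``report`` is a :func:`~dtiprog.lme.progression_report` table whose
    ``metric`` names contain the measure as a ``:``-separated field
    (e.g. ``"All_WM:MD:peak_height"``).  RD and AD metrics are excluded
    regardless of significance.
    """
    out = []
    for _, row in report.iterrows():
        name = row["metric"]
        fields = str(name).split(":")
        measure = next((f for f in fields if f in {"FA", "MD", "RD", "AD"}),
                       None)
        if measure in {"RD", "AD"} or measure is None:
            continue
        if bool(row["significant"]):
            out.append(name)
    if not out:
        raise NoRetainedComponentError(
            "no significant FA/MD metric to enter the PCA")
    return out


def fit_pca_baseline(
    baseline: pd.DataFrame, variables: "list[str] | None" = None
) -> PcaModel:
    """PCA of the baseline metric matrix (subjects x variables).

    Complete cases only; variables are z-scored by their baseline mean
    and SD and the correlation matrix is eigendecomposed.  Retention rule
    is eigenvalue > 1 (strict); a single retained component is used
    unrotated, more than one is promax-rotated.  Each component is
    oriented so its dominant variable loads positively (a deterministic,
    order-independent sign convention).
    """
    if variables is None:
        variables = list(baseline.columns)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    X = baseline[variables].dropna().to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 complete-case subjects")
    underdetermined = n < p
    if underdetermined:
        warnings.warn("fewer subjects than variables; PCA is flagged",
                      UserWarning, stacklevel=2)

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [v for v, s in zip(variables, sds) if s == 0]
        raise ValueError(f"zero-variance variable(s): {bad}")
    Z = (X - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    det = float(np.linalg.det(R))
    collinear = abs(det) < DETERMINANT_GUARD
    if collinear:
        warnings.warn(
            f"correlation matrix determinant {det:.2e} < {DETERMINANT_GUARD}:"
            " multicollinearity", MulticollinearityWarning, stacklevel=2)

    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = int((evals > 1.0).sum())
    if k == 0:
        raise NoRetainedComponentError(
            "no eigenvalue exceeds 1; nothing to retain")

    loadings = evecs[:, :k] * np.sqrt(evals[:k])
    if k > 1:
        rotated, T = promax(loadings, k=4)
        phi = T.T @ T  # factor correlation matrix
        structure = rotated @ phi
        loadings = rotated
    else:
        structure = loadings
    # orient each component so its dominant variable loads positively;
    # anchoring on the largest |loading| makes the sign independent of
    # the order the variables were supplied in
    anchor = np.argmax(np.abs(loadings), axis=0)
    flip = np.where(loadings[anchor, np.arange(loadings.shape[1])] < 0,
                    -1.0, 1.0)
    loadings = loadings * flip
    structure = structure * flip

    # regression-method score coefficients W = R^+ S; the pseudo-inverse
    # coincides with R^-1 when R is invertible and stays defined under
    # perfect collinearity (where it yields the minimum-norm weights)
    W = np.linalg.pinv(R, hermitian=True) @ structure
    return PcaModel(
        variables=list(variables),
        means=means,
        sds=sds,
        corr_determinant=det,
        eigenvalues=evals,
        n_retained=k,
        loadings=loadings,
        score_coefficients=W,
        pct_variance=float(evals[:k].sum() / p * 100.0),
        collinearity_warning=collinear,
        underdetermined=underdetermined,
        n_subjects=n,
    )


def score_visits(model: PcaModel, values: pd.DataFrame) -> np.ndarray:
    """Component scores for any visit's metric matrix.

    Standardization uses the model's *baseline* means and SDs, not the
    visit's own, so follow-up scores are comparable to baseline.
    Returns an (n, k) array (k retained components).
    """
    missing = [v for v in model.variables if v not in values.columns]
    if missing:
        raise KeyError(f"missing variable(s): {missing}")
    X = values[model.variables].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    return Z @ model.score_coefficients


def composite_progression(
    scores: pd.DataFrame,
    *,
    value_col: str = "score",
    time_col: str = "time_years",
    subject_col: str = "subject_id",
) -> LmeFit:
    """Trajectory fit of the composite score (delegates to the LME)."""
    return fit_lme(scores, value_col=value_col, time_col=time_col,
                   subject_col=subject_col)
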