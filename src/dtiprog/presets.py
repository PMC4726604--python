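"""Ready-made cohort configurations.

The SVD preset emulates a symptomatic small-vessel-disease cohort of 99
patients followed annually for three years with 99/96/74/68 usable DTI
scans per visit.  Per-metric truths are set to magnitudes typical of
white-matter histogram metrics in such cohorts: FA median near 0.29
declining by ~0.7%/year, MD median near 8e-4 mm^2 s^-1 rising by
~0.7%/year, MD peak height near 0.015 falling by ~2.4%/year, and CSF MD
metrics with zero true drift (the scanner-stability control).  Random
slopes and residual SDs are sized so the slope standard errors and
residual variances a 99-subject fit produces are of the order observed
in real SVD cohorts.  Latent-factor loadings induce the strong
cross-metric baseline correlations that make a one-component PCA
composite sensible.
"""

from __future__ import annotations

from .synthetic import DEFAULT_RETENTION, CohortConfig, MetricTruth

__all__ = ["svd_cohort_config", "SVD_METRICS", "CSF_METRICS"]

#: All-white-matter histogram metrics with SVD-like progression.
SVD_METRICS: dict[str, MetricTruth] = {
    "All_WM:FA:median": MetricTruth(
        beta0=0.293, beta1=-2.17e-3,
        sd_intercept=0.030, sd_slope=2.6e-3, corr=-0.2,
        sd_resid=6.9e-3,
        intercept_loading=-0.85, slope_loading=-0.6),
    "All_WM:FA:peak_height": MetricTruth(
        # stable metric: true slope indistinguishable from zero
        beta0=3.27e-3, beta1=3.3e-7,
        sd_intercept=3.0e-4, sd_slope=2.3e-5, corr=0.0,
        sd_resid=1.0e-4,
        intercept_loading=-0.4, slope_loading=0.0),
    "All_WM:MD:median": MetricTruth(
        beta0=8.00e-4, beta1=5.36e-6,
        sd_intercept=6.0e-5, sd_slope=3.4e-6, corr=0.2,
        sd_resid=8.9e-6,
        intercept_loading=0.85, slope_loading=0.6),
    "All_WM:MD:peak_height": MetricTruth(
        beta0=1.525e-2, beta1=-3.72e-4,
        sd_intercept=1.5e-3, sd_slope=2.1e-4, corr=-0.2,
        sd_resid=5.2e-4,
        intercept_loading=-0.85, slope_loading=-0.6),
    "All_WM:MD:peak_value": MetricTruth(
        beta0=7.70e-4, beta1=2.85e-6,
        sd_intercept=6.0e-5, sd_slope=3.9e-6, corr=0.2,
        sd_resid=1.05e-5,
        intercept_loading=0.80, slope_loading=0.5),
}

#: CSF mean-diffusivity metrics: no true drift (stability control).
CSF_METRICS: dict[str, MetricTruth] = {
    "CSF:MD:median": MetricTruth(
        beta0=3.00e-3, beta1=0.0,
        sd_intercept=1.0e-4, sd_slope=2.0e-6, corr=0.0,
        sd_resid=2.0e-5),
    "CSF:MD:peak_height": MetricTruth(
        beta0=6.0e-3, beta1=0.0,
        sd_intercept=5.0e-4, sd_slope=1.0e-5, corr=0.0,
        sd_resid=1.0e-4),
}


def svd_cohort_config(
    n_subjects: int = 99,
    seed: int = 0,
    *,
    include_csf: bool = True,
    time_jitter: float = 0.1,
    informative_dropout: float = 0.0,
) -> CohortConfig:
    """The default progressing-SVD cohort."""
    metrics = dict(SVD_METRICS)
    if include_csf:
        metrics.update(CSF_METRICS)
    return CohortConfig(
        n_subjects=n_subjects,
        metrics=metrics,
        visit_times=(0.0, 1.0, 2.0, 3.0),
        retention=DEFAULT_RETENTION,
        seed=seed,
        time_jitter=time_jitter,
        informative_dropout=informative_dropout,
    )
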