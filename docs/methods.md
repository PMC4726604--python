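# Methods

## Scope

`dtiprog` implements a complete longitudinal DTI-histogram analysis for
small-vessel-disease cohorts: scalar-map computation from diffusion
tensors (optionally from simulated DWI), tissue-masked histogram
summary metrics, per-metric linear mixed-effects (LME) trajectories,
slope-difference sample-size estimation with Monte-Carlo verification,
and a baseline-anchored PCA composite. A synthetic cohort generator
with known ground truth stands in for clinical data, so every stage is
testable without any download.

## Tensor scalar maps

The single-tensor model is fitted per voxel by ordinary least squares on
the log-attenuation log(S/S₀) = −b·gᵀDg. Before fitting, each gradient
direction is geometrically averaged with its negative
(√(S₊·S₋)), which cancels imaging-gradient cross-terms, and the b = 0
volumes are arithmetically averaged into S₀. Eigenvalues are sorted
descending; MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2 and
FA = √(3/2)·‖λ−λ̄‖/‖λ‖, with FA ≡ 0 where all eigenvalues vanish.
Negative eigenvalues (possible in noisy log-linear fits) are clamped to
zero for the scalar computation and flagged in a QC mask; this keeps
FA ≤ 1 and diffusivities non-negative while leaving the affected voxels
identifiable. The log-linear (unweighted, non-iterative) estimator was
chosen for determinism; at the noise levels the phantom produces the
difference from weighted fits is immaterial.

## Histogram metrics

Masks take voxels with tissue probability strictly above 0.5 (ties
excluded), then remove voxels with MD > 0.0026 mm²·s⁻¹ from the
parenchymal (GM/NAWM/WMH) masks as CSF-contaminated; the CSF mask is
untouched, and All_WM = NAWM ∪ WMH exactly. Histograms use 1000 bins
over fixed ranges (FA 0–1; diffusivities 0–0.004 mm²·s⁻¹), half-open
bins with a closed last bin, frequencies normalized by the in-range
count.

Of the five metrics, peak value and peak height are necessarily
histogram-based (ties broken toward the lowest bin; the peak location is
reported as that bin's center), while median, moment skewness
(m₃/m₂^1.5) and excess kurtosis (m₄/m₂² − 3; Gaussian → 0) are computed
from the raw in-range voxel values — exact and bin-free. Values outside
the histogram range are excluded from *all five* metrics and reported as
a count, so every metric describes the same sample. Zero-variance
samples flag skew/kurtosis as undefined rather than raising.

## Longitudinal model

Each metric's trajectory is y_it = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)·t_it + ε_it with
unstructured 2×2 random-effect covariance, fitted by full maximum
likelihood (REML available by flag) through statsmodels' `MixedLM`; ML
keeps likelihood comparisons valid and differs negligibly from REML at
~99 subjects. All available observations are used, so dropout and
irregular visit times need no special handling. Numerical choices:

* The response is internally z-scored before fitting and the estimates
  mapped back (an exact reparameterization). The histogram metrics span
  about six orders of magnitude, and raw-scale fits intermittently
  produce singular Hessians inside the optimizer.
* Optimizer cascade lbfgs → cg → powell, keeping the first converged
  fit (or the best likelihood if none converges); lbfgs occasionally
  stalls on nearly singular random-effect covariances that cg/powell
  handle.
* If the full structure still fails, the model falls back to a random
  intercept only and the fit is flagged (`intercept_only`).

The slope is tested with a Wald χ²(1) = (β₁/SE)²; the family-wise
threshold is α/m with m = 21 (five metrics × four measures + one
composite per tissue class), reported both at full precision and
truncated to two significant figures (0.05/21 → 0.0023), the truncated
value being the operative threshold. "Residual error" in the
progression report is the residual *variance* parameter σ̂²_e (σ̂_e is
also exposed), and percentages are 100·β̂₁/β̂₀ and 100·σ̂²_e/β̂₀ relative
to the average intercept.

## Trial sample sizes and the Monte-Carlo oracle

The design is a balanced two-arm, 3-year trial with visits at
t = 0, 1, 2, 3 years (baseline plus three annual follow-ups, mirroring
the cohort's own schedule; configurable). A treatment effect of e%
reduces the mean slope proportionally, Δ = (e/100)·|β₁|, leaving
variance components unchanged. With V = σ²_b1 + σ²_e/Σ(tⱼ−t̄)² the
per-subject slope-estimator variance, the per-arm size is
n = ⌈2(z₁₋α/₂+z₁₋γ)²·V/Δ²⌉ — the ceiling is the minimum integer n
achieving the target power, and n·Δ² is constant across an effect grid
before rounding. Attrition is deliberately *not* built into the
formula; `mc_power` accepts an optional retention schedule for
sensitivity analysis.

`mc_power` verifies the formula by simulating complete trials and
fitting the LME with group, time and group × time fixed effects plus
random intercept and slope, rejecting on the interaction's Wald test.
Because this requires thousands of refits, it uses a dedicated
profiled-likelihood fitter (`_fastlme`) that collapses the data onto
per-stratum sufficient statistics (subjects sharing a visit pattern and
arm) and optimizes only the three Cholesky parameters of the
random-effect covariance, with fixed effects and residual variance
profiled out in closed form. The fitter reproduces statsmodels
`MixedLM` (ML and REML) to ~10⁻⁵ relative error — asserted in the test
suite — at roughly 20 ms per fit instead of ~340 ms.

Variance components in the simulation fit are estimated by REML by
default: full-ML Wald tests are mildly anticonservative at trial sizes
of a few hundred subjects, while the REML-based test's null rejection
rate measured 0.0485 over 6000 replicates. A small residual inflation
(true rate ≈ 0.053 at n = 100/arm) is inherent to referring the Wald
statistic to χ²(1) rather than a finite-df t reference, and is left as
is because χ²(1) is the test the trajectory analysis itself reports.

## PCA composite

Variables entering the PCA are the FA and MD metrics whose slope test
survived Bonferroni correction; RD and AD are always excluded as
sub-parameters of MD whose inclusion drives the correlation-matrix
determinant toward zero (a determinant below 10⁻⁴ raises an explicit
multicollinearity warning; the score weights use the Moore–Penrose
inverse, which equals R⁻¹ whenever R is invertible). Components are
retained if their eigenvalue exceeds 1 (strictly); one retained
component is used unrotated, several are promax-rotated with κ = 4.
Score coefficients use the regression method W = R⁺S (S the structure
matrix), giving baseline scores with mean 0 and variance 1. Each
component is oriented so its dominant variable (largest |loading|)
loads positively — a deterministic convention independent of variable
ordering. Follow-up visits are standardized by the baseline means/SDs,
never their own, and scored with the baseline coefficients. Composite
percentages of the average intercept are expected to be enormous
because baseline scores are centred at zero; they demonstrate why such
percentages are not comparable across centred and uncentred variables.

## Synthetic cohort generator

`simulate_metric_table` draws metric values directly from the LME law
with configurable truth per metric (β₀, β₁, random-intercept/slope SDs
and correlation, residual SD). Design choices:

* **Cohort shape.** Defaults mirror a 99-subject cohort with annual
  visits and monotone dropout leaving 99/96/74/68 scans. Dropout is
  completely at random by default; an informative option tilts dropout
  toward subjects with steeper latent progression, since dropouts in
  such cohorts tend to be the more vulnerable patients.
* **Visit jitter.** Follow-up times are jittered uniformly ±0.1 y
  (baseline fixed at 0) so fits are exercised on irregular times without
  changing the estimand.
* **Random-effect law.** Bivariate Gaussian — matching the model being
  fitted; no heavier-tailed alternative is claimed.
* **Cross-metric correlation.** Per-metric random effects load on two
  cohort-wide latent factors (baseline severity and progression rate),
  producing the strong cross-metric baseline correlations that make a
  one-component PCA meaningful. Loadings are part of the preset.
* **Preset magnitudes.** The SVD preset's intercepts, slopes and
  variance components are set to magnitudes typical of white-matter
  histogram metrics in symptomatic SVD cohorts (FA median ≈ 0.29
  falling ~0.7%/yr; MD median ≈ 8×10⁻⁴ mm²·s⁻¹ rising ~0.7%/yr; MD peak
  height ≈ 0.015 falling ~2.4%/yr; CSF metrics with zero true drift as
  the scanner-stability control). Baseline distributions across
  subjects are plausible choices, not a fit to any specific cohort.

`simulate_phantom_visit` builds voxel-level volumes on a 48³ lattice at
2.5 mm isotropic spacing (desk-scale but at a realistic acquisition
voxel size): a brain ellipsoid with GM shell and WM interior,
ventricular CSF, periventricular WMH blobs whose radius grows ×1.15 per
visit, and a few lacunes. Per-tissue FA/MD values are Gaussian with
per-year drifts (WM FA falls, WM MD rises *and broadens* — the
broadening is what lowers the MD peak height); CSF is static with MD
centred at 3.0×10⁻³ mm²·s⁻¹, deliberately above the 0.0026 filter so
the CSF-exclusion rule is exercised. RD and AD come from an axially
symmetric tensor construction, so MD = (AD+2·RD)/3 holds exactly.
`simulate_dwi` produces the signal S₀·exp(−b·gᵀDg) for 8 b0 volumes
plus 25 Fibonacci-sphere directions and their negatives at
b = 1000 s·mm⁻², with Rician noise via two Gaussian channels (default
SNR(b0) = 20 when enabled).

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: anatomically realistic geometry,
registration and distortion errors, scanner drift and upgrades,
non-Gaussian tissue value distributions, spatially correlated noise,
non-linear trajectories, and measurement error correlated across
metrics within a visit beyond the latent-factor structure. Results on
real cohorts depend on exactly these nuisances; the synthetic suite
establishes the *statistical machinery*, not scanner behaviour.

## Problem sizes and tolerances

The test suite and acceptance script use 2000 replicates for the
power/type-I calibrations (binomial SE ≈ 0.5–0.9 percentage points),
500 cohorts for slope-recovery and interval-coverage checks, and 50
cohorts for the CSF-stability rate — sizes chosen so Monte-Carlo error
is well below the effects being asserted while a full run stays in the
minutes range on one CPU. Oracle-equivalence checks (brute-force
histogram metrics, tensor algebraic identities) assert at 10⁻¹²;
optimizer agreement between the fast fitter and statsmodels asserts at
10⁻⁴–10⁻⁶ relative, reflecting the two optimizers' stopping rules
rather than model disagreement.

## Known limitations

* The log-linear tensor fit is unweighted; at very low SNR its
  eigenvalue bias is larger than weighted/nonlinear alternatives.
* The sample-size formula assumes complete follow-up and equal
  variance components in both arms; violations are explored only
  through `mc_power`'s retention option.
* With a single retained component the promax machinery is bypassed
  entirely (rotation of one factor is the identity), so the oblique
  path is exercised only in multi-component tests.
* Histogram peak statistics inherit bin-width noise by construction;
  the 0.001 / 4×10⁻⁶ widths trade sensitivity against that noise and
  are fixed by convention here.
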