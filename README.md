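# dtiprog

Longitudinal DTI histogram analysis for cerebral small vessel disease
(SVD), built for imaging researchers who want to quantify white-matter
progression, size hypothetical treatment trials around it, and test the
whole analysis chain on synthetic cohorts with known ground truth.

Cerebral SVD damages the brain's white matter diffusely; diffusion
tensor imaging (DTI) picks this up as falling fractional anisotropy (FA)
and rising diffusivity (MD/RD/AD) long before cognitive tests move.
Because the damage is spatially diffuse, the analysis summarizes each
tissue class (normal-appearing white matter, NAWM; white-matter
hyperintensities, WMH; their union All_WM; CSF as a stability control)
by five histogram metrics — **median, peak value, peak height, skew and
excess kurtosis** — computed from 1000-bin normalized histograms
(FA over 0–1, bin width 0.001; diffusivities over 0–0.004 mm²·s⁻¹, bin
width 4×10⁻⁶). Tissue masks take voxels whose class probability exceeds
0.5 and drop parenchymal voxels with MD > 0.0026 mm²·s⁻¹ as
CSF-contaminated.

## The models at the core

**Trajectories.** Each metric is modelled with a linear mixed-effects
model on exact time since baseline (years),

y_it = (β₀ + b₀ᵢ) + (β₁ + b₁ᵢ)·t_it + ε_it,  (b₀ᵢ, b₁ᵢ) ~ N(0, G),  ε_it ~ N(0, σ²_e),

fitted by maximum likelihood with an unstructured 2×2 random-effect
covariance. The annualised change rate β₁ is tested with a Wald χ²(1)
statistic, Bonferroni-corrected across the 21-test family (threshold
0.05/21 → 0.0023). Rates and residual variances are also expressed as
percentages of the average intercept β₀ (the average baseline value).

**Trial sizing.** For a balanced two-arm, 3-year trial with annual
visits, a treatment effect of e% shrinks the mean slope by
Δ = (e/100)·|β₁|, and the per-arm sample size at two-sided α and target
power 1−γ is

n = 2·(z₁₋α/₂ + z₁₋γ)²·V / Δ²,   V = σ²_b1 + σ²_e / Σⱼ(tⱼ − t̄)²,

where V is the variance of one subject's estimated slope (Σ = 5 for
t = 0,1,2,3). A Monte-Carlo oracle (`mc_power`) verifies the formula by
simulating trials and refitting the group × time interaction LME per
replicate.

**Composite score.** PCA on baseline values of the significant FA/MD
metrics (RD/AD excluded as sub-parameters of MD), eigenvalue > 1
retention, promax rotation when more than one component survives, and
regression-method score coefficients. Follow-up visits are standardized
by the *baseline* means/SDs, so the composite's drift measures
progression along the baseline axis.

## Worked example

The bundled synthetic preset emulates a 99-patient SVD cohort scanned at
0/1/2/3 years with 99/96/74/68 usable DTI sessions:

```
dtiprog run --n 99 --seed 1 --out demo
```

produces `metrics.csv`, `fits.csv`, `table3.csv`, `scores.csv`,
`pca_model.yaml` and a run manifest. The fitted trajectories (seed 1):

| metric                 | rate (yr⁻¹) | % annual change | χ²    | significant |
|------------------------|-------------|-----------------|-------|-------------|
| All_WM:FA:median       | −2.53×10⁻³  | −0.86           | 27.8  | yes         |
| All_WM:FA:peak_height  | −6.78×10⁻⁶  | −0.20           | 1.2   | no          |
| All_WM:MD:median       | +3.80×10⁻⁶  | +0.48           | 51.0  | yes         |
| All_WM:MD:peak_height  | −2.73×10⁻⁴  | −1.79           | 58.6  | yes         |
| All_WM:MD:peak_value   | +2.72×10⁻⁶  | +0.36           | 15.8  | yes         |
| CSF:MD:median          | +1.00×10⁻⁷  | +0.003          | 0.007 | no          |
| All_WM:composite:score | −0.114      | (≫100 %)        | 104.2 | yes         |

White-matter anisotropy falls and diffusivity rises while the CSF
control stays flat; the composite's percentage change is enormous only
because baseline scores are centred near zero (the mechanism, not a
meaningful effect size). The PCA retains one component explaining 73.4%
of the baseline variance. Per-arm sample sizes (`table3.csv`, 30/25/20/15%
effects) make MD peak height the most sensitive single metric
(225/324/506/899), with CSF metrics correctly useless (n in the millions).

Library use mirrors the CLI: `simulate_metric_table`, `fit_lme`,
`sample_size`, `mc_power`, `fit_pca_baseline` and friends are plain
functions over pandas DataFrames and numpy arrays; voxel-level phantoms
and a DWI signal generator (`simulate_phantom_visit`, `simulate_dwi`)
exercise the tensor-fitting and masking path end to end.

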