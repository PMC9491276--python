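# Methods

## The coupling model

Let $x_v \in \mathbb{R}^m$ collect the $m \ge 2$ modality intensities at
voxel $v$, after each modality has been globally standardized to mean 0 and
variance 1 over the analysis mask. Around a centre voxel $v_0$, neighbors
$v$ within a cubic window receive Gaussian weights

$$w_v \propto \exp\!\left(-\frac{d(v, v_0)^2}{2\sigma^2}\right),
\qquad \sigma = \frac{\mathrm{FWHM}}{2\sqrt{2\ln 2}},$$

with $d$ the Euclidean distance in millimetres (per-axis voxel dimensions,
so anisotropic grids are handled). Only in-mask neighbors enter; their
weights are renormalized to sum to one. The local weighted covariance is

$$C = \frac{1}{1 - \sum_v w_v^2}\sum_v w_v (x_v - \bar{x}_w)(x_v - \bar{x}_w)^\top,
\qquad \bar{x}_w = \sum_v w_v x_v,$$

and the coupling value is

$$c = \operatorname{logit}\!\left(\frac{p - 1/m}{1 - 1/m}\right),
\qquad p = \frac{\lambda_{\max}(C)}{\operatorname{tr}(C)}.$$

$p$ ranges from $1/m$ (isotropic local cloud) to 1 (rank one), so the
argument of the logit ranges over $[0, 1]$ and $c$ over the whole real
line. The statistic is symmetric in the modalities, invariant to positive
rescaling of any raw modality (through the global standardization), and
invariant to the covariance denominator convention (the eigenvalue
proportion is scale-free).

**Equicorrelation closed form.** For unit variances and common correlation
$\rho \ge 0$, $\lambda_{\max} = 1 + (m-1)\rho$ and
$\operatorname{tr} = m$, so $p = (1 + (m-1)\rho)/m$ and $c =
\operatorname{logit}(\rho)$ exactly, for every $m$. This is the oracle the
validation suite is built on.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fwhm_mm` | 3.0 | Gaussian kernel FWHM in mm; σ ≈ 1.27 mm. Larger values pool more voxels (more stable, less bias, less spatial specificity). |
| neighborhood radius | `round(2·FWHM/voxel_dim)` per axis | Cube half-width in voxels; 7×7×7 at FWHM 3 mm and 11×11×11 at FWHM 5 mm on a 2 mm grid, i.e. truncation at ≈4.7σ. Overridable (`radius_override`) for other conventions. |
| covariance denominator | `1 − Σw²` ("unbiased") | Reliability-weight bias correction; output-irrelevant, stated for reproducibility of intermediate matrices. A "biased" (D = 1) convention is provided and tested to give identical coupling. |
| minimum support | `m + 1` in-mask neighbors | Below this the covariance is rank-deficient by construction and p = 1 is an artifact; the voxel is reported missing (NaN). |
| trace tolerance | 1e-12 | Locally constant neighborhoods are reported missing rather than mapped to an arbitrary proportion. |
| logit clip | 1e-12 | The shifted proportion is clipped to [ε, 1−ε] before the logit so exactly rank-one neighborhoods stay finite; the count of clipped voxels is recorded in the output sidecar. |
| FDR level `q` | 0.05 | BH step-up applied jointly over in-mask voxels, separately per tested effect. |

## Numerical and design choices

- **Mask/edge truncation.** Out-of-mask and out-of-volume neighbors are
  dropped and the remaining weights renormalized — the only choice that
  avoids imputing intensities outside the mask.
- **Kernel normalization.** The full lattice is normalized to sum to one;
  coupling is invariant to this, it is numerical hygiene only.
- **Standardization convention.** Population (divide-by-N) variance over
  mask voxels; any fixed convention gives the same coupling.
- **Implementation.** The per-voxel neighborhood loop is rewritten as
  masked volume convolutions of the modality moments (one per modality
  pair), followed by a batched symmetric eigendecomposition over mask
  voxels. A per-voxel gather path (`extract_neighborhood`) is kept and the
  two are cross-checked in the tests to 1e-9. A whole 30³ volume with three
  modalities runs in well under a second on one CPU; results are
  independent of voxel visit order by construction.
- **Eigenvalue ties.** Only λ_max's value is used, never its eigenvector,
  so exact ties are harmless.
- **WLR estimator.** Implemented from the same weighted covariance
  (slope = C_xy / C_xx), which is algebraically identical to weighted least
  squares with an intercept. Modalities are globally standardized before
  WLR exactly as for pIMCo, for comparability between the estimators. The
  two slopes always satisfy slope_yx · slope_xy = r²_w; a slope is reported
  missing when the independent modality's local weighted variance is below
  1e-12 (the estimator's instability regime). Kendall correlations between
  estimators use the tau-b tie-handling variant, which is robust to clipped
  and repeated values.
- **Group stage.** One joint OLS per voxel (intercept + tested effects +
  nuisance covariates), fit with the subjects having finite coupling at
  that voxel; voxels with fewer than (#parameters + 5) such subjects are
  excluded from inference to avoid unstable mask-fringe fits. Two-level
  factor covariates are coded 0/1 against a configurable reference level.
  BH-FDR is applied per effect over all modeled voxels. Descriptive
  variance uses the sample (N−1) convention.

## The phantom generator

Each voxel of an unsmoothed phantom draws an independent m-vector from a
zero-mean, unit-variance equicorrelated Gaussian with voxel-specific
correlation ρ(v) (one-factor construction
$x_j = \sqrt{\rho}\,z_0 + \sqrt{1-\rho}\,e_j$). Because voxels are iid in
space, the marginal distribution of any interior voxel's coupling value is
exactly that of the estimator applied to one weighted iid sample of the
neighborhood size — which makes the finite-sample behaviour of the
estimator computable by direct Monte-Carlo, independent of the imaging
pipeline. Cohorts add per-subject shifts
ρ_i(v) = ρ(v) + β·(age_i − mean age)·region(v) (and optionally a sex
shift), with a nuisance motion column unrelated to the signal.

What the phantoms deliberately lack: spatial autocorrelation (unless the
optional smoothing is enabled), modality-specific noise spectra, scanner
artifacts, motion, and registration error. Passing recovery tests
establishes the estimator's statistical correctness, not robustness to
those real-data features. Optional Gaussian smoothing adds spatial
autocorrelation but pools neighboring draws and therefore inflates the
realized local correlation; the suite verifies the inflation direction
qualitatively and keeps oracle tests unsmoothed.

## Finite-sample bias and the pre-registered recovery tolerances

The leading sample eigenvalue is biased upward, materially so at the
default kernel: the FWHM 3 mm lattice on a 2 mm grid has effective sample
size $n_\text{eff} = 1/\sum w_v^2 \approx 10.4$. The recovery tests
therefore compare the interior-voxel median coupling against
logit(ρ) with a per-condition tolerance equal to the estimator's median
bias — computed beforehand by direct Monte-Carlo on weighted iid
equicorrelated draws (20 000 draws per condition, fixed seed) — plus a
fixed 0.10 sampling margin. The biases so obtained:

| ρ | m = 2 | m = 3 |
|---|---|---|
| 0.2 | +0.82 | +0.69 |
| 0.5 | +0.23 | +0.15 |
| 0.75 | +0.12 | +0.07 |
| 0.9 | +0.09 | +0.04 |

The bias shrinks as ρ grows (the signal eigenvalue separates from the
noise) and as m grows at fixed ρ. Edge voxels have truncated neighborhoods
and hence larger bias, which is why the recovery tests take the median over
interior voxels (margin of one kernel radius), where the Monte-Carlo
calibration applies exactly.

## Problem sizes in the suite

Validation volumes are 14³–30³ voxels at 2 mm with cohorts of up to 40
synthetic subjects — sizes at which the closed-form and Monte-Carlo oracles
are tight while the full suite runs in well under a minute of compute per
test module. The estimator itself scales linearly in mask voxels and in
m(m+1)/2 convolutions.

## Known limitations

- The coupling value summarizes the covariance shape in one number; with
  m > 2 very different covariance structures can share a value.
- PCA is a linear summary: strong nonlinear (e.g. quadratic) intermodal
  relationships can present as low coupling.
- Cross-sectional only; no longitudinal coupling model.
- Voxel/volume only; no surface (vertex) implementation, and no spatial
  enrichment inference (e.g. spherical spin permutation) — region tables
  report descriptive proportions.
- Exact bit-reproducibility across BLAS builds is not promised; tests and
  recorded summaries use tolerances.
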