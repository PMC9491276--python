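# pimco

Symmetric voxel-wise intermodal coupling for two or more co-registered
volumetric brain images, from local weighted covariance decomposition.

## The problem

When a subject is imaged with several modalities (say cerebral blood flow,
ALFF and ReHo maps on a common grid), biological signal lives not only in
each map but in how the maps covary locally. Earlier voxel-wise coupling
measures used the slope of a locally weighted linear regression of one
modality on the other, which forces a choice of independent variable (the
two choices can disagree badly) and does not extend past two modalities.

pIMCo (PCA-based intermodal coupling) replaces the slope with a symmetric
statistic. At each in-mask voxel, with modalities globally standardized to
mean 0 / variance 1 over the mask:

1. gather the m modality values over a cubic neighborhood, weighting voxels
   by a Gaussian kernel in their Euclidean mm distance from the centre
   (FWHM-parameterized; σ = FWHM / (2√(2 ln 2)));
2. form the m×m weighted covariance matrix C of the neighborhood;
3. take p = λ_max(C) / tr(C), the proportion of local variance explained by
   the first eigenvalue, which ranges from 1/m (spherical cloud, no
   coupling) to 1 (rank one, perfect coupling);
4. map p linearly onto [0, 1] and apply the logit:
   c = logit((p − 1/m)·m/(m−1)).

The result is a single unbounded coupling value per voxel, invariant to
modality order and to the scale of any input map. Under an equal-variance
equicorrelated covariance with correlation ρ, the value is exactly
logit(ρ), for every m. For reference, with three modalities, coupling
values of −2, 0 and 2 correspond to the first eigenvalue explaining 41%,
67% and 92% of the local variance (56%, 75%, 94% with two).

The package also ships the legacy weighted-linear-regression (WLR) slope
estimator and comparison statistics between the two, a group-analysis stage
(voxel-wise mean/variance maps, mass-univariate OLS with nuisance
covariates, Benjamini–Hochberg FDR masks, atlas-region summaries), and a
synthetic phantom generator whose known correlation fields give closed-form
expected coupling for validation.

## Worked example

```python
import numpy as np
from pimco import (PhantomSpec, generate_phantom, build_weight_lattice,
                   compute_pimco, coupling_to_proportion)

# 30x30x30 phantom, 2 mm voxels, three modalities with equicorrelation 0.75
stack = generate_phantom(PhantomSpec(shape=(30, 30, 30), rho=0.75,
                                     n_modalities=3, seed=7))
kernel = build_weight_lattice(fwhm_mm=3.0, voxel_dims_mm=(2.0, 2.0, 2.0))
img = compute_pimco(stack, kernel)

print(round(kernel.sigma_mm, 4))                          # 1.274
print(kernel.side)                                        # (7, 7, 7)
print(round(float(np.nanmedian(img.coupling)), 3))        # 1.177
print(round(float(coupling_to_proportion(
    np.nanmedian(img.coupling), 3)), 3))                  # 0.843
```

A 3 mm FWHM kernel on the 2 mm grid has σ ≈ 1.27 mm and a 7×7×7
neighborhood. The median coupling, 1.177, sits near the population value
logit(0.75) = 1.099; the small upward offset is the finite-sample bias of
the leading eigenvalue at the kernel's effective neighborhood size (~10
voxels), quantified in `docs/methods.md`. The inverse transform says the
median voxel's first eigenvalue explains about 84% of its local variance.

## Command line

```bash
pimco fixtures --out-dir fx --seed 1 --n-subjects 20 --age-effect 0.02
pimco pimco --modality fx/mod0.nii.gz --modality fx/mod1.nii.gz \
      --modality fx/mod2.nii.gz --mask fx/mask.nii.gz --fwhm 3 \
      --out out/coupling.nii.gz
pimco wlr --modality fx/mod0.nii.gz --modality fx/mod1.nii.gz \
      --mask fx/mask.nii.gz --independent 0 --out out/wlr0.nii.gz
pimco group --coupling out/sub-*.nii.gz --covariates fx/covariates.csv \
      --mask fx/mask.nii.gz --effects age,sex --nuisance motion \
      --atlas fx/atlas.nii.gz --out-dir out/group
pimco compare --pimco-img out/coupling.nii.gz --wlr-a out/wlr0.nii.gz \
      --wlr-b out/wlr1.nii.gz --out-dir out/cmp
```

Every NIfTI output carries a JSON sidecar recording the parameters (FWHM,
radius, modality names, clipped-voxel count, software version) needed to
reproduce it.

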