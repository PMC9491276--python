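"""Synthetic multimodal phantoms with known local correlation structure.

Every voxel draws an ``m``-vector from a zero-mean, unit-variance
equicorrelated Gaussian with a voxel-specific target correlation
``rho(voxel)``, via the one-factor construction

    x_j = sqrt(rho) * z0 + sqrt(1 - rho) * e_j

with ``z0`` and ``e_j`` independent standard normals.  Equicorrelation is
the canonical validation structure because the population coupling value is
then exactly ``logit(rho)`` for every modality count — a closed-form oracle
for the whole estimation pipeline.

Optional per-modality Gaussian smoothing adds spatial autocorrelation, at
the cost of perturbing (inflating) the realized local correlation; oracle
tests therefore run unsmoothed.  A cohort generator layers per-subject
covariate effects on the correlation field so the group-analysis stage can
be validated on known signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .coupling import ModalityStack
from .kernels import fwhm_to_sigma

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort", "block_atlas"]


@dataclass
class PhantomSpec:
    """Configuration of one synthetic multimodal volume.

    ``rho`` may be a scalar (constant correlation everywhere) or a full
    per-voxel field in ``[0, 1)``.
    """

    shape: tuple[int, int, int] = (30, 30, 30)
    voxel_dims_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_modalities: int = 3
    rho: float | np.ndarray = 0.5
    smoothing_fwhm_mm: float | None = None
    seed: int = 0
    mask: np.ndarray | None = None


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort for group-analysis validation.

    Per subject ``i``, the correlation field is

        rho_i(v) = base_rho(v) + effect_size * (covariate_i - mean) * region(v)

    with the age covariate drawn uniformly on ``age_range`` (centred before
    scaling so effects do not shift the cohort mean) and sex assigned
    alternately.  ``effect_region`` marks the voxels carrying the effect;
    outside it the field is the base everywhere, giving a built-in null.
    """

    n_subjects: int = 40
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    age_range: tuple[float, float] = (8.0, 22.0)
    age_effect: float = 0.0  # change in rho per year of (centred) age
    sex_effect: float = 0.0  # additive rho shift for the second sex level
    effect_region: np.ndarray | None = None
    seed: int = 0


def _rho_field(rho, shape) -> np.ndarray:
    r = np.asarray(rho, dtype=float)
    if r.ndim == 0:
        r = np.full(shape, float(r))
    if r.shape != tuple(shape):
        raise ValueError(f"rho field shape {r.shape} does not match {shape}")
    if np.any(r < 0) or np.any(r >= 1):
        raise ValueError("rho must lie in [0, 1) everywhere")
    return r


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None) -> ModalityStack:
    """Draw one multimodal stack with the spec's correlation field.

    Deterministic given the spec seed (an explicit ``rng`` overrides it, for
    cohort generation).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    m = spec.n_modalities
    if m < 2:
        raise ValueError("need at least 2 modalities")
    rho = _rho_field(spec.rho, shape)

    z0 = rng.standard_normal(shape)
    vols = np.empty((m,) + shape)
    sq_rho = np.sqrt(rho)
    sq_res = np.sqrt(1.0 - rho)
    for j in range(m):
        vols[j] = sq_rho * z0 + sq_res * rng.standard_normal(shape)

    if spec.smoothing_fwhm_mm is not None:
        sigma_vox = [
            fwhm_to_sigma(spec.smoothing_fwhm_mm) / d for d in spec.voxel_dims_mm
        ]
        for j in range(m):
            vols[j] = ndimage.gaussian_filter(vols[j], sigma_vox)

    mask = spec.mask if spec.mask is not None else np.ones(shape, dtype=bool)
    return ModalityStack(
        volumes=vols,
        mask=mask,
        voxel_dims_mm=spec.voxel_dims_mm,
        modality_names=[f"mod{j}" for j in range(m)],
    )


def block_atlas(shape, n_blocks: int = 2, axis: int = 0) -> np.ndarray:
    """Integer-labeled atlas splitting the grid into equal slabs (labels 1..n)."""
    atlas = np.zeros(shape, dtype=int)
    edges = np.linspace(0, shape[axis], n_blocks + 1).astype(int)
    sl = [slice(None)] * 3
    for i in range(n_blocks):
        sl[axis] = slice(edges[i], edges[i + 1])
        atlas[tuple(sl)] = i + 1
    return atlas


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ModalityStack], pd.DataFrame, np.ndarray]:
    """Generate N subject stacks with covariate-dependent correlation.

    Returns the stacks, a covariate table (``subject``, ``age``, ``sex``,
    plus a nuisance ``motion`` column uncorrelated with the signal), and the
    shared mask.  Raises if any subject's correlation field leaves
    ``[0, 1)``, listing the offending subjects.
    """
    rng = np.random.default_rng(spec.seed)
    ph = spec.phantom
    shape = tuple(ph.shape)
    base = _rho_field(ph.rho, shape)
    region = (
        np.asarray(spec.effect_region).astype(bool)
        if spec.effect_region is not None
        else np.zeros(shape, dtype=bool)
    )
    if region.shape != shape:
        raise ValueError("effect_region grid does not match phantom shape")

    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, size=n)
    sex = np.array(["F", "M"])[np.arange(n) % 2]
    rng.shuffle(sex)
    motion = rng.uniform(0.05, 0.3, size=n)

    age_c = age - age.mean()
    rho_fields = []
    bad = []
    for i in range(n):
        delta = spec.age_effect * age_c[i] + (spec.sex_effect if sex[i] == "M" else 0.0)
        rho_i = base + delta * region
        if np.any(rho_i < 0) or np.any(rho_i >= 1):
            bad.append(i)
        rho_fields.append(rho_i)
    if bad:
        raise ValueError(
            f"covariate effects push rho outside [0, 1) for subjects {bad}"
        )

    stacks = []
    for i in range(n):
        sub_spec = PhantomSpec(
            shape=shape,
            voxel_dims_mm=ph.voxel_dims_mm,
            n_modalities=ph.n_modalities,
            rho=rho_fields[i],
            smoothing_fwhm_mm=ph.smoothing_fwhm_mm,
            mask=ph.mask,
        )
        stacks.append(generate_phantom(sub_spec, rng=rng))

    covariates = pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "motion": motion,
        }
    )
    mask = ph.mask if ph.mask is not None else np.ones(shape, dtype=bool)
    return stacks, covariates, mask
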