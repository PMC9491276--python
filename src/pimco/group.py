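"""Group-level analysis of coupling images.

Descriptive voxel-wise mean/variance maps, mass-univariate linear models
with nuisance covariates (e.g. in-scanner motion), Benjamini-Hochberg FDR
control across voxels, and atlas-region summaries of significant-voxel
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coupling import CouplingImage

__all__ = [
    "CouplingCohort",
    "EffectMaps",
    "GroupResult",
    "descriptive_maps",
    "voxelwise_lm",
    "bh_fdr",
    "region_proportions",
]

#: Voxels modeled with fewer than (number of parameters + this margin)
#: subjects are excluded from inference — fits at mask fringes with barely
#: enough observations are unstable.
MIN_DF_MARGIN = 5


@dataclass
class CouplingCohort:
    """N subject coupling images on a shared grid plus their covariates.

    Attributes
    ----------
    images : numpy.ndarray
        Shape ``(N, nx, ny, nz)``; NaN marks missing voxels.
    covariates : pandas.DataFrame
        One row per subject, aligned with ``images`` by position (or by the
        ``subject`` column if present).
    mask : numpy.ndarray
        Boolean analysis mask.
    """

    images: np.ndarray
    covariates: pd.DataFrame
    mask: np.ndarray

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.images.ndim != 4:
            raise ValueError("images must be (N, nx, ny, nz)")
        if self.mask.shape != self.images.shape[1:]:
            raise ValueError("mask grid does not match images")
        if len(self.covariates) != self.images.shape[0]:
            raise ValueError(
                f"{len(self.covariates)} covariate rows for {self.images.shape[0]} images"
            )
        if "subject" in self.covariates.columns and self.covariates["subject"].duplicated().any():
            raise ValueError("duplicate subject ids in covariate table")

    @classmethod
    def from_images(cls, images, covariates, mask=None) -> "CouplingCohort":
        """Build a cohort from a list of :class:`CouplingImage` (or arrays)."""
        arrs = [im.coupling if isinstance(im, CouplingImage) else np.asarray(im) for im in images]
        stack = np.stack(arrs)
        if mask is None:
            first = images[0]
            if not isinstance(first, CouplingImage):
                raise ValueError("mask is required when images are bare arrays")
            mask = first.mask
        return cls(images=stack, covariates=pd.DataFrame(covariates), mask=mask)

    @property
    def n_subjects(self) -> int:
        return self.images.shape[0]


@dataclass
class EffectMaps:
    """Per-voxel statistics for one modeled effect."""

    estimate: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    sig_mask: np.ndarray | None = None


@dataclass
class GroupResult:
    """Output of the mass-univariate stage."""

    effects: dict[str, EffectMaps]
    model_mask: np.ndarray  # voxels actually modeled
    n_per_voxel: np.ndarray
    design_columns: list[str]
    fdr_q: float | None = None
    info: dict = field(default_factory=dict)


def descriptive_maps(cohort: CouplingCohort) -> tuple[np.ndarray, np.ndarray, float]:
    """Voxel-wise mean and sample variance across subjects.

    Voxels with fewer than two finite subject values are NaN.  Also returns
    the Pearson correlation between the mean and variance maps over voxels
    where both are finite — regions with stronger average coupling often
    show larger between-subject variability, and this scalar summarizes
    that tendency.
    """
    if cohort.n_subjects < 2:
        raise ValueError("descriptive maps need at least 2 subjects")
    imgs = np.where(cohort.mask, cohort.images, np.nan)
    n = np.isfinite(imgs).sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / dof<=0 slices
        mean = np.nanmean(imgs, axis=0)
        var = np.nanvar(imgs, axis=0, ddof=1)
    mean[n < 2] = np.nan
    var[n < 2] = np.nan
    both = np.isfinite(mean) & np.isfinite(var)
    if both.sum() >= 2 and np.ptp(mean[both]) > 0 and np.ptp(var[both]) > 0:
        corr = float(stats.pearsonr(mean[both], var[both]).statistic)
    else:
        corr = float("nan")
    return mean, var, corr


def _build_design(covariates: pd.DataFrame, columns: list[str], sex_reference=None):
    """Intercept + requested columns; two-level object columns become 0/1."""
    parts = {"intercept": np.ones(len(covariates))}
    names = ["intercept"]
    for col in columns:
        if col not in covariates.columns:
            raise ValueError(f"covariate column {col!r} not found")
        s = covariates[col]
        if s.isna().any():
            raise ValueError(f"missing values in covariate {col!r}")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.unique())
            if len(levels) != 2:
                raise ValueError(
                    f"factor covariate {col!r} must have exactly 2 levels, has {levels}"
                )
            ref = sex_reference if sex_reference in levels else levels[0]
            other = [lv for lv in levels if lv != ref][0]
            parts[f"{col}[{other}]"] = (s == other).astype(float).to_numpy()
            names.append(f"{col}[{other}]")
        else:
            parts[col] = s.to_numpy(dtype=float)
            names.append(col)
    X = np.column_stack([parts[nm] for nm in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _ols_fit_block(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y (n x V) on X (n x p); returns beta, se, t, p."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, pvals


def voxelwise_lm(
    cohort: CouplingCohort,
    effects: list[str],
    covariates: list[str] | None = None,
    sex_reference=None,
) -> GroupResult:
    """Ordinary least squares at each voxel, with per-effect two-sided tests.

    One joint model per voxel: intercept + ``effects`` + nuisance
    ``covariates``.  A voxel is fit using only the subjects with a finite
    coupling value there, and is dropped from inference when that count
    falls below ``p + MIN_DF_MARGIN`` parameters.  Subject order does not
    affect the result.

    Parameters
    ----------
    effects : list of str
        Covariate columns whose coefficients are tested and reported.
    covariates : list of str, optional
        Additional nuisance columns included in the design but not reported.
    sex_reference : optional
        Reference level for two-level factor columns (the coefficient is
        reported for the other level).
    """
    covariates = covariates or []
    model_cols = list(effects) + [c for c in covariates if c not in effects]
    X_full, names = _build_design(cohort.covariates, model_cols, sex_reference)
    n, p = X_full.shape
    if n <= p:
        raise ValueError(f"{n} subjects cannot identify {p} parameters")

    effect_names = {}
    for eff in effects:
        matches = [nm for nm in names if nm == eff or nm.startswith(f"{eff}[")]
        if not matches:
            raise ValueError(f"effect {eff!r} not in design")
        effect_names[eff] = matches[0]

    imgs = np.where(cohort.mask, cohort.images, np.nan)
    flat = imgs.reshape(n, -1)
    vox = np.flatnonzero(cohort.mask.ravel())
    Y = flat[:, vox]
    finite = np.isfinite(Y)
    n_per = finite.sum(axis=0)
    min_n = p + MIN_DF_MARGIN
    usable = n_per >= min_n

    shape = cohort.mask.shape
    out = {
        eff: EffectMaps(
            estimate=np.full(shape, np.nan),
            se=np.full(shape, np.nan),
            t=np.full(shape, np.nan),
            p=np.full(shape, np.nan),
        )
        for eff in effects
    }

    # fit voxels in groups sharing the same subject-missingness pattern so
    # each group is one vectorized least-squares solve
    patterns = {}
    for col in np.flatnonzero(usable):
        patterns.setdefault(finite[:, col].tobytes(), []).append(col)
    for key, cols in patterns.items():
        rows = np.frombuffer(key, dtype=bool)
        Xs = X_full[rows]
        if np.linalg.matrix_rank(Xs) < p:
            continue  # pattern leaves the design unidentifiable at these voxels
        beta, se, t, pv = _ols_fit_block(Xs, Y[np.ix_(rows, cols)])
        for eff, nm in effect_names.items():
            j = names.index(nm)
            flat_idx = vox[cols]
            for arr, val in (
                (out[eff].estimate, beta[j]),
                (out[eff].se, se[j]),
                (out[eff].t, t[j]),
                (out[eff].p, pv[j]),
            ):
                arr.ravel()[flat_idx] = val

    model_mask = np.zeros(shape, dtype=bool)
    model_mask.ravel()[vox[usable]] = True
    # voxels whose pattern was rank-deficient stayed NaN; drop them
    any_eff = next(iter(out.values()))
    model_mask &= np.isfinite(any_eff.p)

    n_map = np.zeros(shape, dtype=int)
    n_map.ravel()[vox] = n_per
    return GroupResult(
        effects=out,
        model_mask=model_mask,
        n_per_voxel=n_map,
        design_columns=names,
        info={"n_subjects": n, "n_parameters": p, "min_n_per_voxel": min_n},
    )


def bh_fdr(p_map: np.ndarray, mask: np.ndarray | None = None, q: float = 0.05):
    """Benjamini-Hochberg step-up over the in-mask voxels jointly.

    Returns the adjusted p-value (q-value) map and the binary significance
    mask (adjusted p <= q).  Voxels with NaN p-values are excluded and
    remain NaN / False.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    p_map = np.asarray(p_map, dtype=float)
    sel = np.isfinite(p_map)
    if mask is not None:
        sel &= np.asarray(mask).astype(bool)
    q_map = np.full(p_map.shape, np.nan)
    sig = np.zeros(p_map.shape, dtype=bool)
    pvals = p_map[sel]
    if pvals.size == 0:
        return q_map, sig
    reject, q_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    q_map[sel] = q_adj
    sig[sel] = reject
    return q_map, sig


def region_proportions(
    sig_mask: np.ndarray,
    atlas: np.ndarray,
    analysis_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-atlas-label counts and proportions of significant voxels.

    Labels are non-negative integers with 0 as background.  Counting is
    restricted to the analysis mask; every nonzero atlas label is reported,
    with ``n_voxels = 0`` (and NaN proportion) for labels that do not
    intersect the mask.
    """
    sig_mask = np.asarray(sig_mask).astype(bool)
    atlas = np.asarray(atlas)
    analysis_mask = np.asarray(analysis_mask).astype(bool)
    if not (sig_mask.shape == atlas.shape == analysis_mask.shape):
        raise ValueError("atlas / mask grids are not aligned")
    if np.any(atlas < 0):
        raise ValueError("atlas labels must be non-negative integers")
    if np.any(sig_mask & ~analysis_mask):
        raise ValueError("significance mask extends outside the analysis mask")

    labels = np.unique(atlas)
    labels = labels[labels != 0]
    rows = []
    for lab in labels:
        in_region = (atlas == lab) & analysis_mask
        n_vox = int(in_region.sum())
        n_sig = int((in_region & sig_mask).sum())
        rows.append(
            {
                "label": int(lab),
                "n_voxels": n_vox,
                "n_significant": n_sig,
                "proportion": n_sig / n_vox if n_vox else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["label", "n_voxels", "n_significant", "proportion"])
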