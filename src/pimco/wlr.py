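"""Legacy weighted-linear-regression (WLR) coupling and estimator comparison.

The earlier two-modality coupling definition is the slope of a locally
weighted linear regression of one modality on the other.  It requires
choosing an independent variable and is therefore asymmetric: swapping the
roles gives a different image, and as one slope approaches zero (with the
local weighted r-squared held fixed) the other diverges — the two slopes
always satisfy ``slope_yx * slope_xy = r2``.

This module implements the WLR estimator from the same weighted local
covariance used by pIMCo (algebraically identical to weighted least squares
with an intercept) and the comparison statistics between the two estimators:
per-voxel tables and pairwise Kendall tau-b rank correlations of pIMCo
against a single-reference WLR image and against the voxel-wise maximum
absolute slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import (
    CouplingImage,
    ModalityStack,
    NeighborhoodSample,
    local_covariance_field,
    standardize_global,
    weighted_covariance,
)
from .kernels import KernelSpec

__all__ = ["WlrResult", "wlr_slope", "wlr_fit", "compute_wlr_image", "compare_estimators"]

#: Weighted variance of the independent modality below which the slope is
#: reported as undefined (the instability regime of the legacy estimator).
VAR_TOL = 1e-12


@dataclass(frozen=True)
class WlrResult:
    """Both local WLR slopes and the weighted r-squared they share."""

    slope_y_on_x: float
    slope_x_on_y: float
    weighted_r2: float


def wlr_slope(sample: NeighborhoodSample, independent: int = 0) -> float:
    """Local WLR slope with modality ``independent`` as the regressor.

    Computed as ``C[x, y] / C[x, x]`` from the weighted covariance — the
    closed form of weighted least squares with an intercept (the intercept
    is implicit in the weighted centering).

    Raises
    ------
    ValueError
        If the sample has other than two modalities or the independent
        modality has (near-)zero weighted variance.
    """
    if sample.values.shape[1] != 2:
        raise ValueError("WLR coupling is defined for exactly 2 modalities")
    if independent not in (0, 1):
        raise ValueError("independent must be 0 or 1")
    C = weighted_covariance(sample)
    x = independent
    y = 1 - independent
    if not C[x, x] > VAR_TOL:
        raise ValueError("independent modality has zero weighted variance; slope undefined")
    return float(C[x, y] / C[x, x])


def wlr_fit(sample: NeighborhoodSample) -> WlrResult:
    """Both slopes and the weighted r-squared for one neighborhood."""
    C = weighted_covariance(sample)
    if C.shape != (2, 2):
        raise ValueError("WLR coupling is defined for exactly 2 modalities")
    vx, vy, cxy = C[0, 0], C[1, 1], C[0, 1]
    syx = cxy / vx if vx > VAR_TOL else np.nan
    sxy = cxy / vy if vy > VAR_TOL else np.nan
    r2 = cxy**2 / (vx * vy) if vx > VAR_TOL and vy > VAR_TOL else np.nan
    return WlrResult(slope_y_on_x=float(syx), slope_x_on_y=float(sxy), weighted_r2=float(r2))


def compute_wlr_image(
    stack: ModalityStack,
    kernel: KernelSpec,
    independent: int = 0,
) -> np.ndarray:
    """Voxel-wise WLR slope image for a two-modality stack.

    Uses the same neighborhood, mask-truncation and minimum-support rules as
    the pIMCo computation: a voxel is NaN when out of mask, when fewer than
    ``m + 1 = 3`` in-mask neighbors are available, or when the independent
    modality has zero local weighted variance.  The stack is globally
    standardized first (as for pIMCo) for comparability between estimators.
    """
    if stack.n_modalities != 2:
        raise ValueError("WLR images require exactly 2 modalities")
    if independent not in (0, 1):
        raise ValueError("independent must be 0 or 1")
    if not stack.standardized:
        stack = standardize_global(stack)
    cov, n_in, valid = local_covariance_field(stack, kernel)
    valid = valid & (n_in >= 3)
    x = independent
    y = 1 - independent
    slope = np.full(stack.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = cov[..., x, x]
        ok = valid & np.isfinite(vx) & (vx > VAR_TOL)
        slope[ok] = cov[..., x, y][ok] / vx[ok]
    return slope


def compare_estimators(
    pimco_img: CouplingImage | np.ndarray,
    wlr_img_a: np.ndarray,
    wlr_img_b: np.ndarray,
) -> tuple[pd.DataFrame, dict]:
    """Per-voxel comparison of pIMCo with both single-reference WLR images.

    Returns a table with one row per voxel where all three estimates are
    finite (columns ``voxel``, ``pimco``, ``wlr_a``, ``wlr_b``,
    ``max_abs_wlr``) and a dict of pairwise Kendall tau-b correlations among
    pIMCo, the first-reference WLR and the maximum absolute slope.  Tau
    entries are NaN, with ``degenerate=True``, when an input is constant
    over the compared voxels.
    """
    pimco = pimco_img.coupling if isinstance(pimco_img, CouplingImage) else pimco_img
    pimco = np.asarray(pimco, dtype=float)
    a = np.asarray(wlr_img_a, dtype=float)
    b = np.asarray(wlr_img_b, dtype=float)
    if not (pimco.shape == a.shape == b.shape):
        raise ValueError(
            f"image grids differ: {pimco.shape}, {a.shape}, {b.shape}"
        )
    ok = np.isfinite(pimco) & np.isfinite(a) & np.isfinite(b)
    idx = np.flatnonzero(ok.ravel())
    table = pd.DataFrame(
        {
            "voxel": idx,
            "pimco": pimco.ravel()[idx],
            "wlr_a": a.ravel()[idx],
            "wlr_b": b.ravel()[idx],
        }
    )
    table["max_abs_wlr"] = np.maximum(np.abs(table["wlr_a"]), np.abs(table["wlr_b"]))

    def tau(u, v):
        u = np.asarray(u)
        v = np.asarray(v)
        if len(u) < 2 or np.ptp(u) == 0 or np.ptp(v) == 0:
            return np.nan
        return float(stats.kendalltau(u, v, variant="b").statistic)

    taus = {
        "tau_pimco_wlr_a": tau(table["pimco"], table["wlr_a"]),
        "tau_pimco_max_abs_wlr": tau(table["pimco"], table["max_abs_wlr"]),
        "tau_wlr_a_max_abs_wlr": tau(table["wlr_a"], table["max_abs_wlr"]),
        "n_voxels": int(len(table)),
    }
    taus["degenerate"] = any(
        isinstance(v, float) and np.isnan(v)
        for k, v in taus.items()
        if k.startswith("tau_")
    )
    return table, taus
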