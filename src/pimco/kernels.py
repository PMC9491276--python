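"""Gaussian neighborhood kernels for local coupling estimation.

Coupling is estimated inside a cubic neighborhood around each voxel, with
neighbors down-weighted by a Gaussian in their Euclidean millimetre distance
from the centre.  The kernel is parameterized by its full width at half
maximum (FWHM), the convention used throughout neuroimaging; the standard
deviation follows as ``sigma = FWHM / (2 * sqrt(2 * ln 2))``.

Distances are computed in millimetres using the per-axis voxel dimensions, so
anisotropic grids are handled naturally; on an isotropic grid this reduces to
the usual isotropic kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FWHM_PER_SIGMA",
    "KernelSpec",
    "fwhm_to_sigma",
    "neighborhood_radius",
    "build_weight_lattice",
]

#: FWHM of a Gaussian divided by its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation.

    Parameters
    ----------
    fwhm_mm : float
        Full width at half maximum in mm; must be positive.

    Returns
    -------
    float
        Standard deviation in mm, ``fwhm_mm / (2*sqrt(2*ln 2))``.
        A 3 mm FWHM corresponds to sigma of about 1.27 mm.
    """
    if not fwhm_mm > 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm!r}")
    return fwhm_mm / FWHM_PER_SIGMA


def _as_voxel_dims(voxel_dims_mm) -> tuple[float, float, float]:
    dims = tuple(float(d) for d in np.atleast_1d(voxel_dims_mm))
    if len(dims) == 1:
        dims = dims * 3
    if len(dims) != 3:
        raise ValueError(f"voxel_dims_mm must have 3 entries, got {voxel_dims_mm!r}")
    if any(not d > 0 for d in dims):
        raise ValueError(f"voxel dimensions must be positive, got {dims!r}")
    return dims


def neighborhood_radius(fwhm_mm: float, voxel_dims_mm) -> tuple[int, int, int]:
    """Per-axis neighborhood radius in voxels for a given kernel FWHM.

    The cubic neighborhood spans ``2*r + 1`` voxels along each axis with
    ``r = round(2 * fwhm_mm / voxel_dim)``.  On a 2 mm isotropic grid this
    gives 7x7x7 neighborhoods at FWHM 3 mm and 11x11x11 at FWHM 5 mm, i.e.
    the cube extends to roughly two FWHM (about 4.7 sigma) from the centre,
    beyond which Gaussian weights are negligible.
    """
    if not fwhm_mm > 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm!r}")
    dims = _as_voxel_dims(voxel_dims_mm)
    # round-half-away-from-zero so e.g. 2*3/2 = 3.0 is stable
    return tuple(int(math.floor(2.0 * fwhm_mm / d + 0.5)) for d in dims)


@dataclass(frozen=True)
class KernelSpec:
    """A realized Gaussian weight lattice for one neighborhood configuration.

    Attributes
    ----------
    fwhm_mm : float
        Kernel full width at half maximum in mm.
    sigma_mm : float
        Derived standard deviation in mm.
    radius_voxels : tuple of int
        Per-axis radius; the lattice has shape ``(2r+1,)`` per axis.
    voxel_dims_mm : tuple of float
        Voxel edge lengths in mm used for distance computation.
    weights : numpy.ndarray
        Non-negative lattice centred on the target voxel, normalized to sum
        to one over the full cube.
    """

    fwhm_mm: float
    sigma_mm: float
    radius_voxels: tuple[int, int, int]
    voxel_dims_mm: tuple[float, float, float]
    weights: np.ndarray

    @property
    def side(self) -> tuple[int, int, int]:
        """Neighborhood side length ``2r+1`` per axis."""
        return tuple(2 * r + 1 for r in self.radius_voxels)

    def offsets_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened integer voxel offsets and matching weights.

        Returns an ``(n, 3)`` integer array of offsets from the centre voxel
        and the corresponding length-``n`` weight vector.
        """
        rx, ry, rz = self.radius_voxels
        grid = np.mgrid[-rx : rx + 1, -ry : ry + 1, -rz : rz + 1]
        offsets = grid.reshape(3, -1).T
        return offsets, self.weights.ravel()


def build_weight_lattice(
    fwhm_mm: float,
    voxel_dims_mm,
    radius_override: tuple[int, int, int] | None = None,
) -> KernelSpec:
    """Build the Gaussian weight lattice for a cubic neighborhood.

    The weight at integer offset ``(i, j, k)`` is proportional to
    ``exp(-d^2 / (2 sigma^2))`` where ``d`` is the Euclidean mm distance of
    that offset given the voxel dimensions.  The lattice is truncated at the
    cube edge and renormalized to sum to one; local coupling is invariant to
    this normalization because the eigenvalue proportion is scale-free.

    Parameters
    ----------
    fwhm_mm : float
        Kernel FWHM in mm.
    voxel_dims_mm : sequence of float
        Voxel edge lengths in mm (a scalar is broadcast to three axes).
    radius_override : tuple of int, optional
        Explicit per-axis radius replacing the default sizing rule, for
        reproducing other neighborhood conventions.
    """
    dims = _as_voxel_dims(voxel_dims_mm)
    sigma = fwhm_to_sigma(fwhm_mm)
    if radius_override is not None:
        radius = tuple(int(r) for r in radius_override)
        if any(r < 0 for r in radius):
            raise ValueError(f"radius_override must be non-negative, got {radius!r}")
    else:
        radius = neighborhood_radius(fwhm_mm, dims)

    axes_mm = [np.arange(-r, r + 1, dtype=float) * d for r, d in zip(radius, dims)]
    d2 = (
        axes_mm[0][:, None, None] ** 2
        + axes_mm[1][None, :, None] ** 2
        + axes_mm[2][None, None, :] ** 2
    )
    weights = np.exp(-d2 / (2.0 * sigma**2))
    weights /= weights.sum()
    return KernelSpec(
        fwhm_mm=float(fwhm_mm),
        sigma_mm=sigma,
        radius_voxels=radius,
        voxel_dims_mm=dims,
        weights=weights,
    )
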