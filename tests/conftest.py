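"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the package's vectorized code
paths: covariances are double loops, neighborhood gathering is an explicit
offset loop, and the step-up procedure is written from its definition, so
they can serve as independent checks.
"""

import numpy as np
import pytest

from pimco import ModalityStack, PhantomSpec, build_weight_lattice, generate_phantom


@pytest.fixture(scope="session")
def kernel3():
    """FWHM 3 mm kernel on a 2 mm isotropic grid (7x7x7 lattice)."""
    return build_weight_lattice(3.0, (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def phantom_m3():
    """Small 3-modality equicorrelated phantom with an irregular mask."""
    shape = (22, 20, 18)
    mask = np.ones(shape, dtype=bool)
    mask[:2] = False  # flat face
    x, y, z = np.mgrid[: shape[0], : shape[1], : shape[2]]
    mask &= ((x - 11) / 11.0) ** 2 + ((y - 10) / 10.0) ** 2 + ((z - 9) / 9.0) ** 2 <= 1.2
    mask[8:10, 9:11, 8:10] = False  # interior hole
    spec = PhantomSpec(
        shape=shape, n_modalities=3, rho=0.6, seed=20240117, mask=mask
    )
    return generate_phantom(spec)


def brute_weighted_cov(values, weights):
    """Double-loop weighted covariance with the 1 - sum(w^2) denominator."""
    x = np.asarray(values, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    n, m = x.shape
    mu = np.zeros(m)
    for i in range(n):
        mu += w[i] * x[i]
    C = np.zeros((m, m))
    for i in range(n):
        d = x[i] - mu
        for j in range(m):
            for k in range(m):
                C[j, k] += w[i] * d[j] * d[k]
    return C / (1.0 - np.sum(w**2))


def brute_coupling_at_voxel(stack: ModalityStack, kernel, center):
    """Per-voxel coupling by explicit neighborhood loop (None if degenerate).

    Assumes the stack is already standardized.
    """
    rx, ry, rz = kernel.radius_voxels
    vals, ws = [], []
    for di in range(-rx, rx + 1):
        for dj in range(-ry, ry + 1):
            for dk in range(-rz, rz + 1):
                i, j, k = center[0] + di, center[1] + dj, center[2] + dk
                if not (0 <= i < stack.shape[0] and 0 <= j < stack.shape[1] and 0 <= k < stack.shape[2]):
                    continue
                if not stack.mask[i, j, k]:
                    continue
                vals.append(stack.volumes[:, i, j, k])
                ws.append(kernel.weights[di + rx, dj + ry, dk + rz])
    vals = np.array(vals)
    ws = np.array(ws)
    m = stack.n_modalities
    if len(ws) < m + 1:
        return None
    C = brute_weighted_cov(vals, ws)
    tr = np.trace(C)
    if not tr > 1e-12:
        return None
    p = np.linalg.eigvalsh(C)[-1] / tr
    pu = np.clip((p - 1 / m) * m / (m - 1), 1e-12, 1 - 1e-12)
    return np.log(pu / (1 - pu))


def brute_bh_stepup(pvals, q):
    """Benjamini-Hochberg rejections from the step-up definition."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    n = len(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / n:
            k_max = rank
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_max]] = True
    return reject
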