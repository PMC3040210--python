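"""Sammon's nonlinear multidimensional scaling.

Sammon mapping embeds a distance matrix in few dimensions by minimizing a
stress that normalizes each squared discrepancy by the original distance,
emphasizing the faithful reproduction of *small* distances — the local
neighborhood structure of the observations.  Used here to visualize the
between-genotype geometry of the OPLS-DA predictive scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import EquiscreenError

MAGIC_FACTOR = 0.3
MAX_ITER = 500
MAX_HALVINGS = 30


@dataclass
class SammonEmbedding:
    """2-D (or k-D) coordinates with the stress minimization trajectory."""

    coordinates: np.ndarray
    stress: float
    trajectory: np.ndarray  # stress per accepted iteration, non-increasing


def classical_mds(distances: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS via double centering."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress_and_grad(y: np.ndarray, delta: np.ndarray, c: float):
    """Sammon stress plus its diagonal-Newton update direction."""
    n = y.shape[0]
    diff = y[:, None, :] - y[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(n, 1)
    stress = float(np.sum((delta[iu] - d[iu]) ** 2 / delta[iu]) / c)

    d_safe = np.where(d > 0, d, 1.0)
    np.fill_diagonal(d_safe, 1.0)
    delta_safe = np.where(delta > 0, delta, 1.0)
    np.fill_diagonal(delta_safe, 1.0)

    inv_dd = 1.0 / (delta_safe * d_safe)
    np.fill_diagonal(inv_dd, 0.0)
    gap = delta - d
    # dE/dy_ik = (-2/c) sum_j gap/(delta*d) * (y_ik - y_jk); the second
    # (diagonal-Newton) derivative follows Sammon's original recipe
    g1 = (-2.0 / c) * np.einsum("ij,ijk->ik", gap * inv_dd, diff)
    hess_common = 1.0 + gap / d_safe
    g2 = np.empty_like(y)
    for k in range(y.shape[1]):
        dk2 = diff[:, :, k] ** 2
        term = inv_dd * (gap - dk2 / d_safe * hess_common)
        g2[:, k] = (-2.0 / c) * term.sum(axis=1)
    step = g1 / np.maximum(np.abs(g2), 1e-12)
    return stress, step


def sammon_mds(
    distances: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    max_iter: int = MAX_ITER,
    tol: float = 1e-12,
) -> SammonEmbedding:
    """Minimize Sammon stress by diagonal-Newton descent with step halving.

    The configuration is initialized from classical metric MDS, then moved
    with Sammon's update scaled by the "magic factor" 0.3; whenever a step
    would increase the stress it is halved (up to 30 times), so the
    trajectory of accepted stresses is non-increasing.  Duplicate points
    (zero off-diagonal distances) are jittered with a warning since the
    stress divides by the original distances.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise EquiscreenError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise EquiscreenError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise EquiscreenError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise EquiscreenError("distances must be non-negative")
    n = d.shape[0]
    d = (d + d.T) / 2.0
    iu = np.triu_indices(n, 1)
    if np.any(d[iu] == 0.0):
        warnings.warn("sammon_mds: duplicate points jittered (zero off-diagonal "
                      "distance)", stacklevel=2)
        rng = np.random.default_rng(seed)
        nonzero = d[iu][d[iu] > 0]
        eps = max(1e-8, 1e-4 * float(np.median(nonzero))) if len(nonzero) else 1e-4
        jitter = np.zeros_like(d)
        zero = (d == 0.0)
        np.fill_diagonal(zero, False)
        jitter[zero] = eps * (1.0 + rng.random(int(zero.sum())))
        d = d + (jitter + jitter.T) / 2.0

    c = float(np.sum(d[iu]))
    y = classical_mds(d, dims=dims)
    # degenerate init (all points identical) -> random start
    if np.allclose(y, 0.0):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((n, dims)) * 1e-3

    stress, step = _stress_and_grad(y, d, c)
    trajectory = [stress]
    for _ in range(max_iter):
        accepted = False
        factor = MAGIC_FACTOR
        for _ in range(MAX_HALVINGS):
            y_new = y - factor * step
            new_stress, new_step = _stress_and_grad(y_new, d, c)
            if new_stress <= stress:
                accepted = True
                break
            factor /= 2.0
        if not accepted:
            break
        improvement = stress - new_stress
        y, stress, step = y_new, new_stress, new_step
        trajectory.append(stress)
        if improvement < tol * max(stress, 1e-300) or stress < 1e-30:
            break
    return SammonEmbedding(coordinates=y, stress=stress,
                           trajectory=np.asarray(trajectory))
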