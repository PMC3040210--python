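"""Missing-value-robust principal component analysis (NIPALS).

NIPALS extracts one component at a time by alternating regressions of the
residual matrix on the current score and loading vectors, skipping missing
entries in every inner product.  On complete data it reproduces ordinary
SVD-based PCA; with missing entries it estimates loadings from the observed
cells only.  Loadings of later components are re-orthogonalized against
earlier ones during the iteration so that P'P = I holds also under
missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EquiscreenError

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 5000


@dataclass
class PcaModel:
    """Fitted PCA model.

    loadings:
        variables x components, column-orthonormal.
    scores:
        observations x components.
    explained_variance_ratio:
        fraction of the (observed-entry) total sum of squares captured by
        each component; non-increasing and summing to <= 1.
    center:
        per-column means used for centering.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    n_iter: list

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, x: np.ndarray) -> np.ndarray:
        """Least-squares scores of (possibly incomplete) new rows.

        For complete rows this is the ordinary projection ``(x - mu) P``;
        rows with missing entries are projected by solving the least-squares
        problem on their observed coordinates only.
        """
        x = np.asarray(x, dtype=float)
        xc = x - self.center
        mask = np.isfinite(xc)
        scores = np.empty((x.shape[0], self.n_components))
        complete = mask.all(axis=1)
        if complete.any():
            scores[complete] = np.where(mask[complete], xc[complete], 0.0) @ self.loadings
        for i in np.flatnonzero(~complete):
            obs = mask[i]
            if not obs.any():
                scores[i] = 0.0
                continue
            scores[i], *_ = np.linalg.lstsq(self.loadings[obs], xc[i, obs], rcond=None)
        return scores


def nipals_pca(
    x: np.ndarray,
    n_components: int,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PcaModel:
    """Fit a PCA model by NIPALS, tolerating missing (NaN) entries.

    Each column is centered on the mean of its observed entries.  Component
    ``k`` converges when the relative change of its score vector drops below
    ``tol``; non-convergence raises, naming the component.

    Raises
    ------
    EquiscreenError
        if ``n_components`` exceeds the matrix dimensions, a row or column is
        entirely missing, or a component fails to converge.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise EquiscreenError("nipals_pca expects a 2-D matrix")
    n, p = x.shape
    if not 1 <= n_components <= min(n, p):
        raise EquiscreenError(
            f"n_components={n_components} outside [1, min{x.shape}={min(n, p)}]"
        )
    mask = np.isfinite(x)
    if not mask.any(axis=1).all():
        raise EquiscreenError("every row must have at least one observed entry")
    if not mask.any(axis=0).all():
        raise EquiscreenError("every column must have at least one observed entry")

    center = np.nanmean(np.where(mask, x, np.nan), axis=0)
    resid = np.where(mask, x - center, 0.0)
    total_ss = float(np.sum(resid**2))
    if total_ss == 0.0:
        raise EquiscreenError("matrix has zero variance after centering")

    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    evr = np.zeros(n_components)
    iters: list[int] = []
    ss_prev = total_ss

    for k in range(n_components):
        if ss_prev / total_ss < 1e-14:
            raise EquiscreenError(
                f"component {k + 1}: residual variance exhausted "
                f"(matrix rank < requested components)"
            )
        # init score from the column with the largest residual sum of squares
        j0 = int(np.argmax(np.sum(resid**2, axis=0)))
        t = resid[:, j0].copy()
        if np.linalg.norm(t) == 0.0:
            t = np.ones(n)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            denom_p = mask.T @ (t * t)
            with np.errstate(invalid="ignore", divide="ignore"):
                pvec = (resid.T @ t) / denom_p
            pvec[~np.isfinite(pvec)] = 0.0
            if k:  # keep loadings orthonormal under missingness
                pvec -= loadings[:, :k] @ (loadings[:, :k].T @ pvec)
            nrm = np.linalg.norm(pvec)
            if nrm == 0.0:
                raise EquiscreenError(f"component {k + 1}: degenerate loading vector")
            pvec /= nrm
            denom_t = mask @ (pvec * pvec)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_new = (resid @ pvec) / denom_t
            t_new[~np.isfinite(t_new)] = 0.0
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise EquiscreenError(
                f"NIPALS failed to converge for component {k + 1} "
                f"after {max_iter} iterations"
            )
        resid -= np.where(mask, np.outer(t, pvec), 0.0)
        ss_now = float(np.sum(resid**2))
        loadings[:, k] = pvec
        scores[:, k] = t
        evr[k] = (ss_prev - ss_now) / total_ss
        ss_prev = ss_now
        iters.append(it)

    return PcaModel(loadings=loadings, scores=scores, explained_variance_ratio=evr,
                    center=center, n_iter=iters)
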