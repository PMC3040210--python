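"""Orthogonal projections to latent structures discriminant analysis.

OPLS-DA splits a data matrix's systematic variance into a *predictive* part
correlated with class membership (here: genotype) and an *orthogonal* part
that is systematic but class-unrelated (e.g. harvest drift).  Orthogonal
components are estimated and removed first; PLS2 predictive components are
then fitted on the deflated matrix.  Class prediction uses the nearest
class centroid in predictive-score space, assessed by stratified k-fold
cross-validation and a label-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .io import EquiscreenError

_PLS_TOL = 1e-10
_PLS_MAX_ITER = 5000


@dataclass
class OplsDaModel:
    """Fitted OPLS-DA model.

    Predictive weights/scores/loadings (``w``/``t``/``p``) describe the
    class-correlated variance; orthogonal ones (``w_orth``/``t_orth``/
    ``p_orth``) the class-unrelated systematic variance.  Explained-variance
    fractions of the (centered) data matrix are kept separately for the two
    parts; predictive + orthogonal + residual sums to 1.
    """

    classes: list
    class_labels: np.ndarray
    center: np.ndarray
    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    c: np.ndarray
    w_orth: np.ndarray
    t_orth: np.ndarray
    p_orth: np.ndarray
    r2_predictive: np.ndarray
    r2_orthogonal: np.ndarray
    r2_residual: float
    centroids: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_predictive(self) -> int:
        return self.t.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.t_orth.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Predictive scores for new rows (orthogonal variation removed first).

        Missing entries are imputed with the fitted column means (i.e. they
        contribute zero after centering), matching the fit-time imputation.
        """
        x = np.asarray(x, dtype=float) - self.center
        x = np.where(np.isnan(x), 0.0, x)
        for k in range(self.n_orthogonal):
            to = x @ self.w_orth[:, k]
            x -= np.outer(to, self.p_orth[:, k])
        scores = np.empty((x.shape[0], self.n_predictive))
        for k in range(self.n_predictive):
            t = x @ self.w[:, k]
            scores[:, k] = t
            x -= np.outer(t, self.p[:, k])
        return scores

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Nearest-class-centroid labels in predictive-score space."""
        scores = self.transform(x)
        cent = self.centroids.to_numpy()
        d2 = ((scores[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.centroids.index)[np.argmin(d2, axis=1)]


def _one_hot(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    classes = sorted(set(map(str, labels)))
    y = np.zeros((len(labels), len(classes)))
    for j, cls in enumerate(classes):
        y[:, j] = (labels.astype(str) == cls).astype(float)
    return y, classes


def fit_oplsda(
    x: np.ndarray,
    classes,
    n_predictive: int,
    n_orthogonal: int,
) -> OplsDaModel:
    """Fit an OPLS-DA model of ``x`` (observations x peaks) on class labels.

    Orthogonal components are removed iteratively: each is the part of the
    current PLS loading orthogonal to the span of X'Y, so its score vector
    has exactly zero covariance with every class-indicator column.  PLS2
    predictive components are then extracted from the deflated matrix.
    Missing entries are column-mean imputed with a warning.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(classes)
    if x.shape[0] != len(labels):
        raise EquiscreenError("row count of x must match the class labels")
    y, class_names = _one_hot(labels)
    if len(class_names) < 2:
        raise EquiscreenError("need >=2 classes")
    counts = y.sum(axis=0)
    if (counts < 2).any():
        small = [c for c, n in zip(class_names, counts) if n < 2]
        raise EquiscreenError(f"class(es) with <2 members: {small}")
    if n_predictive > len(class_names) - 1:
        raise EquiscreenError(
            f"n_predictive={n_predictive} exceeds classes-1={len(class_names) - 1}")
    if n_predictive < 1:
        raise EquiscreenError("need at least one predictive component")
    if n_orthogonal < 0:
        raise EquiscreenError("n_orthogonal must be >= 0")
    if np.isnan(x).any():
        warnings.warn("fit_oplsda: missing entries mean-imputed", stacklevel=2)
        col_means = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), col_means, x)

    center = x.mean(axis=0)
    x0 = x - center
    yc = y - y.mean(axis=0)
    total_ss = float(np.sum(x0**2))
    if total_ss == 0:
        raise EquiscreenError("data matrix has zero variance")

    xd = x0.copy()
    w_orth, t_orth, p_orth, r2_orth = [], [], [], []
    for _ in range(n_orthogonal):
        wmat = xd.T @ yc
        basis, svals, _ = np.linalg.svd(wmat, full_matrices=False)
        basis = basis[:, svals > svals[0] * 1e-12] if svals[0] > 0 else basis[:, :0]
        if basis.shape[1] == 0:
            break
        w = basis[:, 0]
        t = xd @ w
        p = xd.T @ t / (t @ t)
        wo = p - basis @ (basis.T @ p)
        nrm = np.linalg.norm(wo)
        if nrm < 1e-12:  # no class-unrelated systematic variance left
            break
        wo /= nrm
        to = xd @ wo
        po = xd.T @ to / (to @ to)
        xd = xd - np.outer(to, po)
        w_orth.append(wo)
        t_orth.append(to)
        p_orth.append(po)
        r2_orth.append(float((to @ to) * (po @ po)) / total_ss)

    # PLS2 (NIPALS) predictive components on the deflated matrix
    ws, ts, ps, cs, r2_pred = [], [], [], [], []
    yd = yc.copy()
    for k in range(n_predictive):
        u = yd[:, int(np.argmax(np.sum(yd**2, axis=0)))].copy()
        if np.linalg.norm(u) < 1e-12:
            raise EquiscreenError(
                f"predictive component {k + 1}: class variance exhausted")
        for _ in range(_PLS_MAX_ITER):
            w = xd.T @ u
            w /= np.linalg.norm(w)
            t = xd @ w
            c = yd.T @ t / (t @ t)
            u_new = yd @ c / (c @ c)
            if np.linalg.norm(u_new - u) / max(np.linalg.norm(u_new), 1e-300) < _PLS_TOL:
                u = u_new
                break
            u = u_new
        else:
            raise EquiscreenError(f"PLS did not converge for component {k + 1}")
        p = xd.T @ t / (t @ t)
        xd = xd - np.outer(t, p)
        yd = yd - np.outer(t, c)
        ws.append(w)
        ts.append(t)
        ps.append(p)
        cs.append(c)
        r2_pred.append(float((t @ t) * (p @ p)) / total_ss)

    t_pred = np.column_stack(ts)
    model = OplsDaModel(
        classes=class_names,
        class_labels=labels,
        center=center,
        w=np.column_stack(ws), t=t_pred, p=np.column_stack(ps),
        c=np.column_stack(cs),
        w_orth=np.column_stack(w_orth) if w_orth else np.zeros((x.shape[1], 0)),
        t_orth=np.column_stack(t_orth) if t_orth else np.zeros((x.shape[0], 0)),
        p_orth=np.column_stack(p_orth) if p_orth else np.zeros((x.shape[1], 0)),
        r2_predictive=np.asarray(r2_pred),
        r2_orthogonal=np.asarray(r2_orth),
        r2_residual=float(np.sum(xd**2)) / total_ss,
    )
    cent = pd.DataFrame(t_pred).groupby(pd.Series(labels.astype(str), name="class")).mean()
    model.centroids = cent.loc[class_names]
    return model


def cross_validate(
    x: np.ndarray,
    classes,
    n_predictive: int,
    n_orthogonal: int,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Stratified k-fold cross-validated accuracy and confusion matrix.

    Folds are assigned by ``seed`` (bit-stable for a fixed seed); the model
    is refit per fold and held-out samples are predicted by nearest class
    centroid.  Rows of the confusion matrix are true classes, columns
    predicted.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(list(map(str, classes)))
    class_names = sorted(set(labels))
    counts = pd.Series(labels).value_counts()
    if counts.min() < folds:
        raise EquiscreenError(
            f"smallest class has {counts.min()} members; use folds <= {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    confusion = pd.DataFrame(0, index=class_names, columns=class_names)
    for train, test in skf.split(x, labels):
        model = fit_oplsda(x[train], labels[train], n_predictive, n_orthogonal)
        pred = model.predict(x[test])
        for truth, guess in zip(labels[test], pred):
            confusion.loc[truth, guess] += 1
    accuracy = float(np.trace(confusion.to_numpy()) / len(labels))
    return accuracy, confusion


def accuracy_by_components(
    x: np.ndarray,
    classes,
    max_predictive: int,
    n_orthogonal: int = 0,
    folds: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Cross-validated accuracy for each predictive-component count."""
    accs = {}
    for k in range(1, max_predictive + 1):
        accs[k], _ = cross_validate(x, classes, k, n_orthogonal, folds=folds, seed=seed)
    return pd.Series(accs, name="cv_accuracy")


@dataclass
class PermutationResult:
    """Label-permutation test of the cross-validated accuracy."""

    accuracy: float
    m: int
    b: int                # permutations with accuracy >= the original
    p: float              # (b + 1) / (m + 1)
    permuted_accuracies: np.ndarray = field(repr=False, default=None)


def permutation_test(
    x: np.ndarray,
    classes,
    n_predictive: int,
    n_orthogonal: int,
    m: int = 1000,
    folds: int = 5,
    seed: int = 0,
) -> PermutationResult:
    """Shuffle class labels ``m`` times, recomputing cross-validated accuracy.

    The empirical p-value is ``(b + 1) / (m + 1)`` where ``b`` counts
    permutations whose accuracy matched or beat the original labels'.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(map(str, classes)))
    accuracy, _ = cross_validate(x, labels, n_predictive, n_orthogonal,
                                 folds=folds, seed=seed)
    perm_acc = np.empty(m)
    for i in range(m):
        shuffled = rng.permutation(labels)
        fold_seed = int(rng.integers(2**31 - 1))
        perm_acc[i], _ = cross_validate(x, shuffled, n_predictive, n_orthogonal,
                                        folds=folds, seed=fold_seed)
    b = int(np.sum(perm_acc >= accuracy))
    return PermutationResult(accuracy=accuracy, m=m, b=b, p=(b + 1) / (m + 1),
                             permuted_accuracies=perm_acc)


def correlation_loadings(model: OplsDaModel, x: np.ndarray, peak_ids=None) -> pd.DataFrame:
    """Pearson correlation of each peak's profile with each predictive score.

    Zero-variance peaks get NaN.  Values lie in [-1, 1]; peaks close to
    +-1 on a component are the ones that component describes well.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n != model.t.shape[0]:
        raise EquiscreenError("x must be the matrix the model was fitted on")
    cols = {}
    for k in range(model.n_predictive):
        t = model.t[:, k]
        tc = t - t.mean()
        rs = np.full(x.shape[1], np.nan)
        for j in range(x.shape[1]):
            xj = x[:, j]
            obs = np.isfinite(xj)
            if obs.sum() < 3:
                continue
            xc = xj[obs] - xj[obs].mean()
            denom = np.linalg.norm(xc) * np.linalg.norm(tc[obs])
            if denom > 0:
                rs[j] = float(xc @ tc[obs] / denom)
        cols[f"tp{k + 1}"] = rs
    index = pd.Index(peak_ids if peak_ids is not None else range(x.shape[1]),
                     name="peak_id")
    return pd.DataFrame(cols, index=index)


def loading_concordance(loadings_a: pd.Series, loadings_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of two loading vectors over shared keys.

    Tests whether two independently fitted models rank the same metabolites
    as discriminative.  Returns ``(rho, one-sided p)`` for the alternative
    rho > 0.  Requires >=5 shared metabolites.
    """
    shared = loadings_a.index.intersection(loadings_b.index)
    if len(shared) < 5:
        raise EquiscreenError(f"only {len(shared)} shared metabolites; need >=5")
    res = stats.spearmanr(loadings_a.loc[shared], loadings_b.loc[shared],
                          alternative="greater")
    return float(res.statistic), float(res.pvalue)
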