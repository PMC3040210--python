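"""Chemical-diversity coverage via PCA of physicochemical descriptors.

How representative is the set of *detected* metabolites of a whole reference
metabolome?  Both sets are described by the same physicochemical descriptors
(vapor pressure, logP, molecular weight, polar surface area, ...).  A PCA
model is fitted to the detected subset, and coverage is the percentage of
the reference set's descriptor-space variance captured by projecting the
reference matrix onto the subset's loadings: descriptor directions along
which the detected metabolites vary are "covered", directions they never
explore are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EquiscreenError, _read_csv
from .pca import nipals_pca

#: the 18 descriptors used throughout: log vapor pressure, octanol:water
#: partition/distribution coefficients, bioconcentration and adsorption
#: coefficients, molecular volume/refractivity/weight, rotatable bonds,
#: boiling/flash temperatures, enthalpy of vaporization, polar surface area,
#: H-bond donors/acceptors, surface tension, density, index of refraction.
DESCRIPTORS = (
    "LgPVap", "LgP", "LgD-7", "BCF-7", "KOC", "MVol", "MR", "MW", "Rot",
    "Tb", "Tf", "HVap", "PArea", "HDon", "HAcc", "SrfTen", "D", "IoR",
)

#: descriptors spanning orders of magnitude that are log-transformed before
#: scaling (vapor pressure by default)
LOG_DESCRIPTORS = ("LgPVap",)


@dataclass
class ScalingRecord:
    """Standardization parameters so subsets can reuse the reference's."""

    log_columns: tuple
    center: pd.Series
    scale: pd.Series


@dataclass
class PropertyMatrix:
    """Metabolites x descriptors matrix (missing entries allowed)."""

    data: pd.DataFrame
    scaling: ScalingRecord | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise EquiscreenError("duplicate descriptor names")

    @property
    def standardized(self) -> bool:
        return self.scaling is not None

    @property
    def descriptors(self) -> list:
        return list(self.data.columns)


def load_property_matrix(path) -> PropertyMatrix:
    """Read a descriptor CSV: metabolite key column followed by descriptors."""
    df = _read_csv(path, index_col=0).astype(float)
    return PropertyMatrix(df)


def standardize_properties(
    raw: PropertyMatrix,
    record: ScalingRecord | None = None,
    log_columns: tuple = LOG_DESCRIPTORS,
) -> PropertyMatrix:
    """Log-transform selected columns, then center and unit-variance scale.

    With ``record`` given (from a previously standardized reference), its
    log columns, means and scales are applied instead of the matrix's own,
    so a subset lives in the same coordinate system as the reference.

    Raises if a log column has non-positive observed values or a column is
    constant over its observed entries.
    """
    if raw.standardized:
        raise EquiscreenError("property matrix is already standardized")
    df = raw.data.astype(float).copy()
    if record is not None:
        log_columns = record.log_columns
    for col in log_columns:
        if col in df.columns:
            if (df[col] <= 0).any():
                raise EquiscreenError(f"descriptor {col!r} must be positive for log transform")
            df[col] = np.log10(df[col])
    if record is None:
        center = df.mean(axis=0)
        scale = df.std(axis=0, ddof=1)
        constant = scale.isna() | (scale <= 0)
        if constant.any():
            raise EquiscreenError(
                f"constant descriptor(s): {list(scale.index[constant])}"
            )
        record = ScalingRecord(tuple(log_columns), center, scale)
    else:
        center = record.center.reindex(df.columns)
        scale = record.scale.reindex(df.columns)
        if center.isna().any():
            raise EquiscreenError("scaling record does not cover all descriptors")
    return PropertyMatrix((df - center) / scale, scaling=record)


def _projection_residual_ss(xc: np.ndarray, loadings: np.ndarray) -> tuple[float, float]:
    """Observed-entry SS of the residual after projecting rows onto ``loadings``.

    Rows with missing entries are projected by least squares on their
    observed coordinates; missing cells contribute to neither sum.
    Returns ``(SS_residual, SS_total)``.
    """
    mask = np.isfinite(xc)
    x0 = np.where(mask, xc, 0.0)
    ss_total = float(np.sum(x0**2))
    complete = mask.all(axis=1)
    ss_resid = 0.0
    if complete.any():
        xb = x0[complete]
        resid = xb - (xb @ loadings) @ loadings.T
        ss_resid += float(np.sum(resid**2))
    for i in np.flatnonzero(~complete):
        obs = mask[i]
        if not obs.any():
            continue
        li = loadings[obs]
        ti, *_ = np.linalg.lstsq(li, xc[i, obs], rcond=None)
        ss_resid += float(np.sum((xc[i, obs] - li @ ti) ** 2))
    return ss_resid, ss_total


def chemical_coverage(
    reference: PropertyMatrix,
    subset: PropertyMatrix,
    n_components: int,
) -> float:
    """Percentage of reference descriptor variance predicted by the subset.

    A PCA model (missing-tolerant NIPALS, centered on the subset's own
    means) is fitted to the subset; the centered reference matrix ``X`` is
    projected on its loadings ``P`` and coverage is
    ``100 * (1 - SS(X - X P P') / SS(X))`` with missing cells skipped in
    both sums.  ``X`` is centered on the reference's own column means.
    """
    if not (reference.standardized and subset.standardized):
        raise EquiscreenError("standardize both matrices first (subset with the "
                              "reference's scaling record)")
    if subset.descriptors != reference.descriptors:
        raise EquiscreenError("descriptor sets (and order) must match")
    if subset.data.shape[0] < n_components:
        raise EquiscreenError(
            f"subset has {subset.data.shape[0]} metabolites; cannot fit "
            f"{n_components} components"
        )
    model = nipals_pca(subset.data.to_numpy(dtype=float), n_components)
    x = reference.data.to_numpy(dtype=float)
    col_means = np.nanmean(x, axis=0)
    ss_resid, ss_total = _projection_residual_ss(x - col_means, model.loadings)
    return 100.0 * (1.0 - ss_resid / ss_total)


def default_n_components(subset: PropertyMatrix, target_variance: float = 0.95) -> int:
    """Smallest component count reaching ``target_variance`` of subset variance.

    Capped at descriptors - 1 (and at metabolites - 1).
    """
    cap = min(len(subset.descriptors) - 1, subset.data.shape[0] - 1)
    model = nipals_pca(subset.data.to_numpy(dtype=float), cap)
    cum = np.cumsum(model.explained_variance_ratio)
    reached = np.flatnonzero(cum >= target_variance)
    return int(reached[0] + 1) if len(reached) else cap


def coverage_report(
    reference: PropertyMatrix,
    subsets: dict[str, PropertyMatrix],
    n_components: int | str = "auto",
) -> pd.DataFrame:
    """Coverage of the reference by each subset and by their union.

    One row per subset plus a ``union`` row (all subset metabolites pooled).
    The union's coverage is checked against the per-subset maximum and the
    comparison reported in the ``ge_max_individual`` column.
    """
    rows = []
    union_frames = []
    for name, sub in subsets.items():
        k = default_n_components(sub) if n_components == "auto" else int(n_components)
        rows.append({"subset": name, "n_metabolites": sub.data.shape[0],
                     "n_components": k,
                     "coverage_pct": chemical_coverage(reference, sub, k)})
        union_frames.append(sub.data)
    if union_frames:
        union_df = pd.concat(union_frames, axis=0)
        union_df = union_df[~union_df.index.duplicated(keep="first")]
        union = PropertyMatrix(union_df, scaling=reference.scaling)
        k = default_n_components(union) if n_components == "auto" else int(n_components)
        cov_union = chemical_coverage(reference, union, k)
        best = max(r["coverage_pct"] for r in rows)
        rows.append({"subset": "union", "n_metabolites": union.data.shape[0],
                     "n_components": k, "coverage_pct": cov_union,
                     "ge_max_individual": bool(cov_union >= best - 1e-9)})
    else:
        rows.append({"subset": "reference", "n_metabolites": reference.data.shape[0],
                     "n_components": len(reference.descriptors),
                     "coverage_pct": 100.0})
    return pd.DataFrame(rows)
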