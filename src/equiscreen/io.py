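"""Data model and file I/O for peak tables, study designs and annotations.

A *peak table* is a samples x peaks matrix of positive abundances with
missing entries, as produced by a single analytical platform (GC-MS, LC-MS
or CE-MS) after instrument-level preprocessing.  The *study design* records
the experimental factors for every sample: genotype, its role in the
substantial-equivalence comparison (control line, transgenic line, or
traditional reference cultivar), ripening stage, treatment, harvest order
and replicate number.  An *annotation map* links peak ids to namespaced
metabolite identifiers (compound names, KEGG, CAS, ChemSpider, or
platform-local library ids).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("GC-MS", "LC-MS", "CE-MS", "fused")
ROLES = ("control", "transgenic", "reference")
NAMESPACES = ("name", "KEGG", "CAS", "ChemSpider", "platform-local")

#: cell contents treated as a missing abundance when reading delimited text
MISSING_TOKENS = ("", "NA", "NaN", "nan")


class EquiscreenError(ValueError):
    """Raised on invalid inputs anywhere in the package."""


@dataclass
class PeakTable:
    """Samples x peaks abundance matrix with missing entries allowed.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and peak ids as columns.  Missing
        abundances are NaN.  Raw (untransformed) tables must be strictly
        positive where observed.
    platform:
        One of ``GC-MS``, ``LC-MS``, ``CE-MS`` or ``fused``.
    transformed:
        Whether :func:`preprocess` (log + autoscaling) has been applied.
    """

    data: pd.DataFrame
    platform: str
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise EquiscreenError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise EquiscreenError(f"duplicate sample ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise EquiscreenError(f"duplicate peak ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        if not self.transformed:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if np.any(values <= 0):
                    raise EquiscreenError(
                        "raw peak table must be strictly positive where observed"
                    )
        else:
            if np.any(np.isinf(values)):
                raise EquiscreenError("transformed peak table contains infinities")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def peak_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-peak fraction of missing entries."""
        return self.data.isna().mean(axis=0)


@dataclass
class StudyDesign:
    """Per-sample experimental factors.

    ``table`` is indexed by sample id with columns ``genotype``, ``role``,
    ``stage``, ``treatment``, ``harvest_order`` and ``replicate``.  Exactly
    one genotype must carry the ``control`` role.
    """

    table: pd.DataFrame

    REQUIRED = ("genotype", "role", "stage", "treatment", "harvest_order", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise EquiscreenError(f"study design missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise EquiscreenError("duplicate sample ids in study design")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise EquiscreenError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        controls = self.table.loc[self.table["role"] == "control", "genotype"].unique()
        if len(controls) != 1:
            raise EquiscreenError(
                f"exactly one genotype must have role 'control', found {list(controls)}"
            )
        role_by_geno = self.table.groupby("genotype")["role"].nunique()
        if (role_by_geno > 1).any():
            bad = role_by_geno[role_by_geno > 1].index.tolist()
            raise EquiscreenError(f"genotype(s) with conflicting roles: {bad}")

    @property
    def control(self) -> str:
        """Genotype label of the control line."""
        return self.table.loc[self.table["role"] == "control", "genotype"].iloc[0]

    @property
    def transgenic_lines(self) -> list:
        return sorted(self.table.loc[self.table["role"] == "transgenic", "genotype"].unique())

    @property
    def reference_cultivars(self) -> list:
        return sorted(self.table.loc[self.table["role"] == "reference", "genotype"].unique())

    @property
    def stages(self) -> list:
        return sorted(self.table["stage"].unique())

    def samples_of(self, genotype: str, stage: str | None = None) -> list:
        mask = self.table["genotype"] == genotype
        if stage is not None:
            mask &= self.table["stage"] == stage
        return list(self.table.index[mask])

    def check_matches(self, table: PeakTable) -> None:
        """Every sample of ``table`` must appear exactly once in the design."""
        missing = set(table.sample_ids) - set(self.table.index)
        if missing:
            raise EquiscreenError(f"samples absent from study design: {sorted(missing)}")


@dataclass
class AnnotationMap:
    """peak id -> set of ``(namespace, value)`` metabolite identifiers."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for peak, idents in self.entries.items():
            for ns, value in idents:
                if not ns or not str(value):
                    raise EquiscreenError(
                        f"malformed identifier for peak {peak!r}: {(ns, value)!r}"
                    )
                if ns not in NAMESPACES:
                    raise EquiscreenError(
                        f"unknown namespace {ns!r} for peak {peak!r}; expected {NAMESPACES}"
                    )
        self.entries = {peak: set(idents) for peak, idents in self.entries.items()}

    def get(self, peak_id) -> set:
        return self.entries.get(peak_id, set())

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def merge(maps) -> "AnnotationMap":
        """Union several maps (peak ids must not collide across maps)."""
        out: dict = {}
        for m in maps:
            for peak, idents in m.entries.items():
                out.setdefault(peak, set()).update(idents)
        return AnnotationMap(out)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_csv(path, **kw):
    sep = kw.pop("sep", None)
    return pd.read_csv(path, sep=sep, engine="python", comment="#",
                       skip_blank_lines=True, **kw)


def load_peak_table(path, platform: str, transformed: bool = False) -> PeakTable:
    """Read a delimited peak table: header row of peak ids, first column sample ids.

    Cells are numeric or one of the missing tokens (empty, ``NA``, ``NaN``).
    Duplicate ids, negative abundances (for raw tables) and ragged rows
    raise.  Pass ``transformed=True`` when re-loading an already log-scaled
    table (e.g. a fused consensus table written by this package).
    """
    header = _read_csv(path, header=None, nrows=1)
    peak_ids = [str(v) for v in header.iloc[0, 1:]]
    if len(set(peak_ids)) != len(peak_ids):
        dup = sorted({p for p in peak_ids if peak_ids.count(p) > 1})
        raise EquiscreenError(f"{path}: duplicate peak ids: {dup}")
    df = _read_csv(path, index_col=0, na_values=list(MISSING_TOKENS),
                   keep_default_na=False)
    if df.isna().all(axis=None) and df.size == 0:
        raise EquiscreenError(f"{path}: empty peak table")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise EquiscreenError(f"{path}: non-numeric cell in peak table ({exc})") from exc
    return PeakTable(df, platform=platform, transformed=transformed)


def write_peak_table(table: PeakTable, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.data.to_csv(fh, na_rep="NA")


def load_design(path) -> StudyDesign:
    df = _read_csv(path, index_col=0)
    df["harvest_order"] = df["harvest_order"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    for col in ("genotype", "role", "stage", "treatment"):
        df[col] = df[col].astype(str)
    return StudyDesign(df)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, index_label="sample_id")


def load_annotation_map(path) -> AnnotationMap:
    """Read a two-column CSV ``peak_id, namespace:value`` (several rows per peak)."""
    df = _read_csv(path, header=0)
    entries: dict = {}
    for peak, ident in zip(df.iloc[:, 0], df.iloc[:, 1]):
        ns, _, value = str(ident).partition(":")
        if not _:
            raise EquiscreenError(f"identifier {ident!r} lacks a 'namespace:value' form")
        entries.setdefault(peak, set()).add((ns, value))
    return AnnotationMap(entries)


def write_annotation_map(amap: AnnotationMap, path) -> None:
    rows = [(peak, f"{ns}:{value}")
            for peak, idents in sorted(amap.entries.items(), key=lambda kv: str(kv[0]))
            for ns, value in sorted(idents)]
    pd.DataFrame(rows, columns=["peak_id", "identifier"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pre-analysis transformation
# ---------------------------------------------------------------------------

def preprocess(table: PeakTable, max_missing_fraction: float = 0.30) -> PeakTable:
    """Missingness filter, log10 transform, and per-peak autoscaling.

    Peaks with a missing fraction strictly greater than ``max_missing_fraction``
    are excluded.  Remaining abundances are log10-transformed, then each peak
    is centered and scaled to unit variance over its observed entries (ddof=1).
    Peaks whose observed values are constant after the log transform are
    dropped with a warning since autoscaling is undefined for them.
    """
    if table.transformed:
        raise EquiscreenError("peak table is already transformed")
    keep = table.missing_fraction() <= max_missing_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("preprocess: dropped %d/%d peaks with >%.0f%% missing values",
                    dropped, table.n_peaks, 100 * max_missing_fraction)
    data = np.log10(table.data.loc[:, keep.index[keep]])
    sd = data.std(axis=0, ddof=1)
    constant = sd.isna() | (sd <= 0)
    if constant.any():
        bad = list(sd.index[constant])
        warnings.warn(
            f"preprocess: excluded {len(bad)} zero-variance peak(s) "
            f"(autoscaling undefined): {bad[:5]}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
        data = data.loc[:, ~constant]
        sd = sd[~constant]
    scaled = (data - data.mean(axis=0)) / sd
    return replace(table, data=scaled, transformed=True)
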