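"""Cross-platform identifier unification and consensus data fusion.

Peaks measured on different platforms but annotated with the same metabolite
identifiers are grouped by connected components of the identifier-sharing
graph.  Within each group, well-correlated peaks are replaced by their first
principal component (missing-tolerant NIPALS), giving a single consensus
peak per metabolite; poorly correlated groups are left as duplicates.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import AnnotationMap, EquiscreenError, PeakTable
from .pca import nipals_pca

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.5
#: groups whose members share fewer common observed samples than this are
#: left as duplicates — a Pearson correlation on <3 points is meaningless
MIN_COMMON_SAMPLES = 3

_NAMESPACE_PREFERENCE = ("name", "KEGG", "CAS", "ChemSpider", "platform-local")


@dataclass
class IdentifierGroup:
    """Peaks linked (transitively) by shared metabolite identifiers."""

    members: list            # peak ids
    platforms: dict          # peak id -> platform label
    canonical: str           # chosen namespaced identifier, e.g. "KEGG:C00049"
    evidence: set = field(default_factory=set)  # identifiers that linked members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusTable:
    """Fused peak table plus per-fused-peak provenance.

    ``provenance`` has one row per fused peak: source peaks, within-group
    mean pairwise Pearson correlation, whether the group was summarized to
    its first principal component, and the sign applied to that component.
    """

    table: PeakTable
    provenance: pd.DataFrame
    n_unique_metabolites: int
    n_peaks: int


def unify_identifiers(maps: dict[str, AnnotationMap]) -> list[IdentifierGroup]:
    """Group peaks across platforms via shared namespaced identifiers.

    Groups are the connected components of the graph whose nodes are peaks
    and whose edges join any two peaks sharing an identifier (any
    namespace).  Unannotated peaks form singleton groups.
    """
    graph = nx.Graph()
    platform_of: dict = {}
    ident_index: dict = {}
    for platform, amap in maps.items():
        for peak, idents in amap.entries.items():
            if peak in platform_of:
                raise EquiscreenError(f"peak id {peak!r} appears on several platforms")
            platform_of[peak] = platform
            graph.add_node(peak)
            for ident in idents:
                ident_index.setdefault(ident, []).append(peak)
    for ident, peaks in ident_index.items():
        for a, b in zip(peaks, peaks[1:]):
            graph.add_edge(a, b, ident=ident)

    groups = []
    for component in nx.connected_components(graph):
        members = sorted(component, key=str)
        idents: set = set()
        for peak in members:
            idents |= maps[platform_of[peak]].get(peak)
        shared = {i for i in idents if sum(i in maps[platform_of[m]].get(m) for m in members) > 1}
        groups.append(IdentifierGroup(
            members=members,
            platforms={m: platform_of[m] for m in members},
            canonical=_canonical_identifier(idents, members),
            evidence=shared,
        ))
    return sorted(groups, key=lambda g: str(g.members[0]))


def _canonical_identifier(idents: set, members: list) -> str:
    for ns in _NAMESPACE_PREFERENCE:
        vals = sorted(v for n, v in idents if n == ns)
        if vals:
            return f"{ns}:{vals[0]}"
    return f"peak:{members[0]}"


def mean_pairwise_correlation(sub: pd.DataFrame) -> tuple[float, int]:
    """Mean pairwise-complete Pearson r over all column pairs.

    Returns ``(mean r, smallest common-sample count over pairs)``.
    """
    cols = list(sub.columns)
    rs = []
    min_common = sub.shape[0]
    for a, b in itertools.combinations(cols, 2):
        pair = sub[[a, b]].dropna()
        min_common = min(min_common, len(pair))
        if len(pair) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            if np.isfinite(r):
                rs.append(r)
    return (float(np.mean(rs)) if rs else np.nan), min_common


def summarize_group(
    sub: pd.DataFrame,
    group: IdentifierGroup,
    r_min: float = DEFAULT_R_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Summarize one identifier group of preprocessed (scaled) peaks.

    Singleton groups pass through.  Larger groups whose mean pairwise
    Pearson correlation reaches ``r_min`` are replaced by their first
    NIPALS principal component, rescaled to unit variance, with the sign
    fixed so the consensus correlates positively with the member mean
    profile.  Poorly correlated groups (or groups sharing fewer than
    three common observed samples) are left as duplicates.
    """
    if sub.shape[1] != len(group.members):
        raise EquiscreenError("sub-table columns do not match group members")
    if len(group) == 1:
        prov = {"source_peaks": list(group.members), "mean_pairwise_r": np.nan,
                "summarized": False, "sign": 1}
        return sub, prov

    mean_r, min_common = mean_pairwise_correlation(sub)
    prov = {"source_peaks": list(group.members), "mean_pairwise_r": mean_r,
            "summarized": False, "sign": 1}
    if min_common < MIN_COMMON_SAMPLES:
        warnings.warn(
            f"group {group.canonical}: members share only {min_common} common "
            f"observed samples; left as duplicates", stacklevel=2)
        return sub, prov
    if not np.isfinite(mean_r) or mean_r < r_min:
        return sub, prov

    values = sub.to_numpy(dtype=float)
    row_obs = np.isfinite(values).any(axis=1)  # consensus is missing where no member was observed
    model = nipals_pca(values[row_obs], 1)
    consensus = np.full(len(sub), np.nan)
    consensus[row_obs] = model.scores[:, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        member_mean = np.nanmean(values, axis=1)
    obs = np.isfinite(member_mean) & np.isfinite(consensus)
    sign = 1
    if obs.sum() >= 2 and np.corrcoef(consensus[obs], member_mean[obs])[0, 1] < 0:
        sign = -1
        consensus = -consensus
    sd = np.nanstd(consensus, ddof=1)
    if sd > 0:
        consensus = (consensus - np.nanmean(consensus)) / sd
    fused = pd.DataFrame({group.canonical: consensus}, index=sub.index)
    prov.update(summarized=True, sign=sign)
    return fused, prov


def fuse(
    tables: dict[str, PeakTable],
    maps: dict[str, AnnotationMap],
    r_min: float = DEFAULT_R_MIN,
) -> ConsensusTable:
    """Concatenate per-platform tables and collapse same-annotation peaks.

    All tables must share an identical sample set (order may differ).
    Returns the fused table with per-fused-peak provenance and counts of
    unique annotated metabolites and total fused peaks.
    """
    if not tables:
        raise EquiscreenError("no peak tables to fuse")
    sample_sets = {pl: set(t.sample_ids) for pl, t in tables.items()}
    ref_platform = next(iter(tables))
    ref = sample_sets[ref_platform]
    for pl, s in sample_sets.items():
        if s != ref:
            only_a = sorted(map(str, ref - s))
            only_b = sorted(map(str, s - ref))
            raise EquiscreenError(
                f"sample sets differ between {ref_platform} and {pl}: "
                f"only in {ref_platform}: {only_a}; only in {pl}: {only_b}"
            )
    order = tables[ref_platform].sample_ids
    concat = pd.concat([t.data.reindex(order) for t in tables.values()], axis=1)

    # every surviving peak becomes a graph node: unannotated ones as
    # singletons; annotations for peaks dropped upstream are ignored
    full_maps = {}
    for pl, t in tables.items():
        src = maps[pl].entries if pl in maps else {}
        entries = {peak: set(src.get(peak, ())) for peak in t.peak_ids}
        full_maps[pl] = AnnotationMap(entries)

    groups = unify_identifiers(full_maps)
    fused_cols: list[pd.DataFrame] = []
    prov_rows: list[dict] = []
    n_annotated = 0
    for group in groups:
        if not group.canonical.startswith("peak:"):
            n_annotated += 1
        sub = concat[group.members]
        fused, prov = summarize_group(sub, group, r_min=r_min)
        prov["fused_peaks"] = list(fused.columns)
        prov["canonical"] = group.canonical
        fused_cols.append(fused)
        prov_rows.append(prov)

    fused_df = pd.concat(fused_cols, axis=1)
    provenance = pd.DataFrame(prov_rows)
    table = PeakTable(fused_df, platform="fused", transformed=True)
    logger.info("fuse: %d peaks -> %d fused peaks (%d annotated metabolites)",
                concat.shape[1], fused_df.shape[1], n_annotated)
    return ConsensusTable(table=table, provenance=provenance,
                          n_unique_metabolites=n_annotated,
                          n_peaks=fused_df.shape[1])


def cross_platform_correlation(
    tables: dict[str, PeakTable],
    maps: dict[str, AnnotationMap],
) -> tuple[pd.Series, float]:
    """Average pairwise Pearson r for metabolites detected on >1 platform.

    Returns a per-metabolite series of mean pairwise correlations (indexed
    by canonical identifier) and their grand mean.  With no multi-platform
    metabolite the series is empty and the grand mean NaN.
    """
    groups = unify_identifiers({pl: m for pl, m in maps.items()})
    order = tables[next(iter(tables))].sample_ids
    concat = pd.concat([t.data.reindex(order) for t in tables.values()], axis=1)
    per_met = {}
    for group in groups:
        platforms = set(group.platforms.values())
        if len(platforms) < 2:
            continue
        members = [m for m in group.members if m in concat.columns]
        if len(members) < 2:
            continue
        # only pairs straddling two platforms count as cross-platform evidence
        rs = []
        for a, b in itertools.combinations(members, 2):
            if group.platforms[a] == group.platforms[b]:
                continue
            pair = concat[[a, b]].dropna()
            if len(pair) >= 2:
                r = float(np.corrcoef(pair[a], pair[b])[0, 1])
                if np.isfinite(r):
                    rs.append(r)
        if rs:
            per_met[group.canonical] = float(np.mean(rs))
    series = pd.Series(per_met, dtype=float).sort_index()
    grand = float(series.mean()) if len(series) else float("nan")
    return series, grand
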