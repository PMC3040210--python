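import numpy as np
import pandas as pd
import pytest

from equiscreen import (
    AnnotationMap,
    EquiscreenError,
    PeakTable,
    SimulationConfig,
    cross_platform_correlation,
    fuse,
    generate_study,
    preprocess,
    summarize_group,
    unify_identifiers,
)
from equiscreen.fusion import IdentifierGroup


def amap(platform_entries):
    return {pl: AnnotationMap(entries) for pl, entries in platform_entries.items()}


class TestUnifyIdentifiers:
    def test_shared_kegg_groups_pair(self):
        maps = amap({"GC-MS": {"A": {("KEGG", "C00049")}},
                     "LC-MS": {"B": {("KEGG", "C00049")}}})
        groups = unify_identifiers(maps)
        assert len(groups) == 1
        assert sorted(groups[0].members) == ["A", "B"]
        assert groups[0].canonical == "KEGG:C00049"

    def test_transitive_closure(self):
        # A shares CAS with B, B shares KEGG with C; A and C share nothing
        maps = amap({"GC-MS": {"A": {("CAS", "56-84-8")}},
                     "LC-MS": {"B": {("CAS", "56-84-8"), ("KEGG", "C00049")}},
                     "CE-MS": {"C": {("KEGG", "C00049")}}})
        groups = unify_identifiers(maps)
        assert len(groups) == 1
        assert sorted(groups[0].members) == ["A", "B", "C"]

    def test_unannotated_peaks_are_singletons(self):
        maps = amap({"GC-MS": {f"p{i}": set() for i in range(5)}})
        groups = unify_identifiers(maps)
        assert len(groups) == 5
        assert all(len(g) == 1 for g in groups)


class TestSummarizeGroup:
    def group(self, members, platform="GC-MS"):
        return IdentifierGroup(members=list(members),
                               platforms={m: platform for m in members},
                               canonical="KEGG:C1")

    def test_identical_columns_collapse_to_unit_copy(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(30)
        sub = pd.DataFrame({"a": col, "b": col})
        fused, prov = summarize_group(sub, self.group("ab"))
        assert prov["summarized"]
        consensus = fused.iloc[:, 0]
        assert np.corrcoef(consensus, col)[0, 1] > 1 - 1e-10
        assert abs(consensus.std(ddof=1) - 1) < 1e-10

    def test_poorly_correlated_pair_left_as_duplicates(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(200)
        b = 0.1 * a + np.sqrt(1 - 0.01) * rng.standard_normal(200)
        fused, prov = summarize_group(pd.DataFrame({"a": a, "b": b}),
                                      self.group("ab"), r_min=0.5)
        assert not prov["summarized"]
        assert list(fused.columns) == ["a", "b"]

    def test_consensus_beats_single_members(self):
        # three noisy copies of one latent profile: their first PC should
        # track the latent more closely than any individual copy does
        rng = np.random.default_rng(2)
        latent = rng.standard_normal(100)
        cols = {f"m{i}": latent + 0.5 * rng.standard_normal(100) for i in range(3)}
        sub = pd.DataFrame(cols)
        fused, prov = summarize_group(sub, self.group(list(cols)))
        assert prov["summarized"]
        r_consensus = abs(np.corrcoef(fused.iloc[:, 0], latent)[0, 1])
        r_members = max(abs(np.corrcoef(sub[c], latent)[0, 1]) for c in cols)
        assert r_consensus > r_members

    def test_too_few_common_samples_warns(self):
        a = np.array([1.0, 2.0, np.nan, np.nan, 0.5])
        b = np.array([np.nan, np.nan, 1.0, 2.0, 0.7])
        with pytest.warns(UserWarning, match="common"):
            fused, prov = summarize_group(pd.DataFrame({"a": a, "b": b}),
                                          self.group("ab"))
        assert not prov["summarized"]


class TestFuse:
    def tables(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        t1 = PeakTable(pd.DataFrame(rng.standard_normal((n, 3)),
                                    index=idx, columns=["g1", "g2", "g3"]),
                       platform="GC-MS", transformed=True)
        t2 = PeakTable(pd.DataFrame(rng.standard_normal((n, 2)),
                                    index=idx, columns=["l1", "l2"]),
                       platform="LC-MS", transformed=True)
        return {"GC-MS": t1, "LC-MS": t2}

    def test_disjoint_annotations_concatenate(self):
        tables = self.tables()
        maps = amap({"GC-MS": {"g1": {("KEGG", "C1")}},
                     "LC-MS": {"l1": {("KEGG", "C2")}}})
        result = fuse(tables, maps)
        assert result.n_peaks == 5

    def test_empty_annotations_keep_all_peaks(self):
        tables = self.tables()
        maps = amap({"GC-MS": {}, "LC-MS": {}})
        result = fuse(tables, maps)
        assert result.n_peaks == 5
        assert result.n_unique_metabolites == 0

    def test_differing_sample_sets_rejected(self):
        tables = self.tables()
        tables["LC-MS"].data.index = [f"x{i}" for i in range(20)]
        with pytest.raises(EquiscreenError, match="sample sets differ"):
            fuse(tables, amap({"GC-MS": {}, "LC-MS": {}}))

    def test_never_increases_peak_count_and_partitions_sources(self, small_study):
        tables, _, maps, _ = small_study
        pre = {pl: preprocess(t) for pl, t in tables.items()}
        result = fuse(pre, maps)
        total_in = sum(t.n_peaks for t in pre.values())
        assert result.n_peaks <= total_in
        sources = [p for row in result.provenance["source_peaks"] for p in row]
        assert len(sources) == total_in          # every source peak accounted for
        assert len(set(sources)) == total_in     # ... exactly once

    def test_platform_order_only_permutes_columns(self):
        tables = self.tables()
        maps = amap({"GC-MS": {}, "LC-MS": {}})
        a = fuse(dict(tables), maps)
        b = fuse(dict(reversed(list(tables.items()))), maps)
        assert set(a.table.peak_ids) == set(b.table.peak_ids)
        pd.testing.assert_frame_equal(a.table.data[sorted(a.table.peak_ids)],
                                      b.table.data[sorted(b.table.peak_ids)])


class TestCrossPlatformCorrelation:
    def test_duplicated_platform_gives_unity(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(30)]
        data = pd.DataFrame(rng.standard_normal((30, 2)), index=idx,
                            columns=["a1", "a2"])
        data2 = data.copy()
        data2.columns = ["b1", "b2"]
        tables = {"GC-MS": PeakTable(data, "GC-MS", transformed=True),
                  "LC-MS": PeakTable(data2, "LC-MS", transformed=True)}
        maps = amap({"GC-MS": {"a1": {("KEGG", "C1")}, "a2": {("KEGG", "C2")}},
                     "LC-MS": {"b1": {("KEGG", "C1")}, "b2": {("KEGG", "C2")}}})
        series, grand = cross_platform_correlation(tables, maps)
        assert len(series) == 2
        assert grand == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_correlation(self):
        # with all design effects off, cross-platform correlation on the log
        # scale equals the planted shared-noise fraction
        cfg = SimulationConfig(
            n_transgenic=1, n_reference=1, n_stages=1, n_replicates=17,
            peaks_per_platform={"GC-MS": 30, "LC-MS": 30, "CE-MS": 30},
            n_shared_metabolites=20, cross_platform_rho=0.6,
            stage_effect_sd=0.0, cultivar_effect_sd=0.0, harvest_drift_sd=0.0,
            n_gm_peaks=0, random_missing=0.0, censor_quantile=0.0, seed=21)
        tables, _, maps, _ = generate_study(cfg)
        pre = {pl: preprocess(t) for pl, t in tables.items()}
        _, grand = cross_platform_correlation(pre, maps)
        assert grand == pytest.approx(0.6, abs=0.1)

    def test_single_platform_annotations_give_empty_result(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(10)]
        tables = {"GC-MS": PeakTable(pd.DataFrame(rng.standard_normal((10, 1)),
                                                  index=idx, columns=["a"]),
                                     "GC-MS", transformed=True)}
        series, grand = cross_platform_correlation(
            tables, amap({"GC-MS": {"a": {("KEGG", "C1")}}}))
        assert series.empty
        assert np.isnan(grand)
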