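import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from equiscreen import (
    EquiscreenError,
    PeakTable,
    estimate_margin,
    ks_normality,
    run_safety,
    safety_summary,
    tost_safety,
    welch_ci,
)
from equiscreen.safety import SafetyMargin

from conftest import make_design


TOY_A = np.array([1.2, 1.9, 1.5])   # reference cultivar replicates
TOY_B = np.array([0.4, 0.6, 0.2])   # control replicates


def hand_welch_ci(a, b, level=0.90):
    """Explicit Welch CI from first principles (test-side oracle)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = stats.t.ppf(0.5 + level / 2, df)
    delta = ma - mb
    return delta, delta - t * np.sqrt(se2), delta + t * np.sqrt(se2)


class TestMargins:
    def test_welch_ci_matches_hand_oracle(self):
        delta, lo, hi, _, _ = welch_ci(TOY_A, TOY_B, level=0.90)
        e_delta, e_lo, e_hi = hand_welch_ci(TOY_A, TOY_B)
        assert delta == pytest.approx(e_delta, abs=1e-10)
        assert lo == pytest.approx(e_lo, abs=1e-10)
        assert hi == pytest.approx(e_hi, abs=1e-10)

    def test_symmetric_margin_is_max_abs_ci_bound(self):
        margin = estimate_margin(TOY_B, {"cv": TOY_A}, peak_id="p", stage="red")
        _, e_lo, e_hi = hand_welch_ci(TOY_A, TOY_B)
        expected = max(abs(e_lo), abs(e_hi))
        assert margin.margin_high == pytest.approx(expected, abs=1e-10)
        assert margin.margin_low == pytest.approx(-expected, abs=1e-10)
        assert margin.defining_cultivar == "cv"

    def test_furthest_cultivar_selected_by_mean_difference(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 0.1, 6)
        refs = {"near": rng.normal(0.2, 0.1, 6), "far": rng.normal(2.0, 0.1, 6)}
        margin = estimate_margin(ctrl, refs)
        assert margin.defining_cultivar == "far"
        # symmetric margin always contains the defining mean difference
        delta_far = refs["far"].mean() - ctrl.mean()
        assert margin.margin_high >= abs(delta_far)

    def test_asymmetric_envelope_contains_each_ci(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(0, 0.3, 6)
        refs = {f"c{i}": rng.normal(mu, 0.3, 6) for i, mu in enumerate([-1, 0.5, 2])}
        margin = estimate_margin(ctrl, refs, mode="asymmetric")
        for v in refs.values():
            _, lo, hi = hand_welch_ci(v, ctrl)
            assert margin.margin_low <= lo + 1e-12
            assert margin.margin_high >= hi - 1e-12

    def test_identical_panel_shrinks_margin_to_zero(self):
        ctrl = np.array([1.0, 1.0 + 1e-9, 1.0 - 1e-9, 1.0])
        refs = {"same": ctrl + 1e-9}
        margin = estimate_margin(ctrl, refs)
        assert margin.margin_high < 1e-6

    def test_no_usable_cultivar_raises(self):
        with pytest.raises(EquiscreenError, match="no reference cultivar"):
            estimate_margin(TOY_B, {"cv": np.array([1.0])})


class TestTost:
    def margin(self, low=-1.0, high=1.0):
        return SafetyMargin("p", "s", low, high, "cv")

    def test_equal_means_tiny_variance_declared_safe(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.01, 6)
        b = rng.normal(0, 0.01, 6)
        res = tost_safety(a, b, self.margin())
        assert res.declared_safe
        assert res.p < 1e-10

    def test_large_shift_not_declared(self):
        rng = np.random.default_rng(3)
        a = rng.normal(5.0, 0.01, 6)
        b = rng.normal(0.0, 0.01, 6)
        res = tost_safety(a, b, self.margin())
        assert not res.declared_safe
        assert res.p > 0.999

    def test_degenerate_zero_variance(self):
        a = np.array([1.0, 1.0, 1.0])
        b = np.array([1.0, 1.0, 1.0])
        res = tost_safety(a, b, self.margin())
        assert res.degenerate_variance
        assert res.declared_safe and res.p == 0.0
        out = tost_safety(a + 5.0, b, self.margin())
        assert out.degenerate_variance and not out.declared_safe and out.p == 1.0

    def test_p_is_max_of_one_sided(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0.5, 1, 8), rng.normal(0, 1, 8)
        res = tost_safety(a, b, self.margin())
        assert res.p == max(res.p_lower, res.p_upper)
        assert 0 <= res.p <= 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=1.01, max_value=10.0),
           seed=st.integers(min_value=0, max_value=2**20))
    def test_enlarging_margins_never_revokes_safety(self, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0.2, 0.5, 6), rng.normal(0, 0.8, 7)
        small = self.margin(-0.8, 0.8)
        big = self.margin(-0.8 * scale, 0.8 * scale)
        if tost_safety(a, b, small).declared_safe:
            assert tost_safety(a, b, big).declared_safe

    def test_power_increases_with_replicates(self):
        rng = np.random.default_rng(5)
        n_rep = 400
        rates = []
        for n in (4, 8, 16):
            hits = sum(
                tost_safety(rng.normal(0, 1, n), rng.normal(0, 1, n),
                            self.margin(-1.5, 1.5)).declared_safe
                for _ in range(n_rep))
            rates.append(hits / n_rep)
        assert rates[0] <= rates[1] <= rates[2]


class TestKsNormality:
    def test_too_few_residuals(self):
        with pytest.raises(EquiscreenError, match=">=3"):
            ks_normality([0.1, -0.1])

    def test_normal_residuals_rarely_flagged(self):
        rng = np.random.default_rng(6)
        ps = [ks_normality(rng.standard_normal(500)) for _ in range(100)]
        assert np.mean(np.asarray(ps) > 0.05) >= 0.90

    def test_exponential_residuals_flagged(self):
        rng = np.random.default_rng(7)
        assert ks_normality(rng.exponential(1.0, 1000)) < 0.01


class TestStudyLevel:
    def build_study(self, effects, seed=8, replicates=8, noise=0.05):
        """Peak table with per-genotype mean shifts given by ``effects``."""
        design = make_design({"CTRL": "control", "TG": "transgenic",
                              "R1": "reference", "R2": "reference"},
                             replicates=replicates, seed=seed)
        rng = np.random.default_rng(seed)
        n_peaks = 30
        values = rng.normal(0, noise, (len(design.table), n_peaks))
        for geno, shift in effects.items():
            mask = (design.table["genotype"] == geno).to_numpy()
            values[mask] += shift
        df = pd.DataFrame(values, index=design.table.index,
                          columns=[f"p{j}" for j in range(n_peaks)])
        return PeakTable(df, platform="fused", transformed=True), design

    def test_null_study_mostly_safe(self):
        table, design = self.build_study({"R1": 0.6, "R2": -0.5})
        results = run_safety(table, design)
        summary, incon = safety_summary(results)
        assert (summary["safe_fraction"] > 0.9).all()
        # the inconclusive list is exactly the failing (peak, line, stage) rows
        failing = results[results["margin_defined"] & ~results["declared_safe"]]
        assert len(incon) == len(failing)
        assert set(incon["peak_id"]) == set(failing["peak_id"])

    def test_shifted_line_fails(self):
        table, design = self.build_study({"R1": 0.3, "R2": -0.3, "TG": 2.0})
        results = run_safety(table, design)
        summary, _ = safety_summary(results)
        assert (summary["safe_fraction"] < 0.1).all()

    def test_hypothetical_panel_orders_cultivars(self):
        # a cultivar identical to the control must look at least as safe as
        # one with a genuine shift
        table, design = self.build_study({"R1": 0.0, "R2": 1.0}, noise=0.05)
        results = run_safety(table, design, hypothetical_panel=True)
        summary, _ = safety_summary(results)
        by_line = summary.groupby("line")["safe_fraction"].mean()
        assert by_line["R1"] >= by_line["R2"]
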