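import numpy as np
import pandas as pd
import pytest

from equiscreen import (
    EquiscreenError,
    accuracy_by_components,
    correlation_loadings,
    cross_validate,
    fit_oplsda,
    loading_concordance,
    permutation_test,
)


def three_class_data(seed=0, n_per=20, p=30, shift=1.5):
    rng = np.random.default_rng(seed)
    labels = np.repeat(["a", "b", "c"], n_per)
    x = rng.standard_normal((3 * n_per, p))
    x[labels == "a", :3] += shift
    x[labels == "b", 3:6] += shift
    return x, labels


def two_class_batch_data(seed=1, n_per=20, p=500):
    """Two classes differing on 10 peaks, plus a strong batch direction."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["ctrl", "gm"], n_per)
    x = rng.standard_normal((2 * n_per, p))
    x[labels == "gm", :10] += 2.0
    batch = rng.standard_normal(2 * n_per)
    batch -= batch.mean()
    # batch loading avoids the class-effect peaks so it is class-unrelated
    direction = np.zeros(p)
    direction[10:60] = 3.0
    x += np.outer(batch, direction / np.linalg.norm(direction) * 12)
    return x, labels, batch


class TestFit:
    def test_matches_plsda_oracle_without_orthogonal(self):
        from sklearn.cross_decomposition import PLSRegression

        x, labels = three_class_data()
        model = fit_oplsda(x, labels, n_predictive=2, n_orthogonal=0)
        y = pd.get_dummies(labels).to_numpy(dtype=float)
        oracle = PLSRegression(n_components=2, scale=False).fit(x, y)
        for k in range(2):
            r = np.corrcoef(model.t[:, k], oracle.x_scores_[:, k])[0, 1]
            assert abs(r) > 1 - 1e-6

    def test_orthogonal_scores_uncorrelated_with_classes(self):
        x, labels, _ = two_class_batch_data()
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=2)
        y = pd.get_dummies(labels).to_numpy(dtype=float)
        yc = y - y.mean(axis=0)
        assert np.abs(model.t_orth.T @ yc).max() < 1e-8
        assert np.abs(model.t.T @ model.t_orth).max() < 1e-8

    def test_orthogonal_component_captures_batch(self):
        x, labels, batch = two_class_batch_data()
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=1)
        r_batch = np.corrcoef(model.t_orth[:, 0], batch)[0, 1]
        assert abs(r_batch) > 0.9
        gm = labels == "gm"
        within = np.sqrt((model.t[gm, 0].var() + model.t[~gm, 0].var()) / 2)
        assert abs(model.t[gm, 0].mean() - model.t[~gm, 0].mean()) > 4 * within

    def test_explained_variance_partitions_total(self):
        x, labels = three_class_data(seed=2)
        model = fit_oplsda(x, labels, n_predictive=2, n_orthogonal=3)
        total = (model.r2_predictive.sum() + model.r2_orthogonal.sum()
                 + model.r2_residual)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_validation_errors(self):
        x, labels = three_class_data()
        with pytest.raises(EquiscreenError, match="classes-1"):
            fit_oplsda(x, labels, n_predictive=3, n_orthogonal=0)
        with pytest.raises(EquiscreenError, match=">=2 classes"):
            fit_oplsda(x, ["same"] * len(labels), n_predictive=1, n_orthogonal=0)
        small = np.asarray(labels).copy()
        small[0] = "rare"
        small[1:] = "common"
        with pytest.raises(EquiscreenError, match="<2 members"):
            fit_oplsda(x, small, n_predictive=1, n_orthogonal=0)

    def test_missing_entries_imputed_with_warning(self):
        x, labels = three_class_data(seed=3)
        x[0, 0] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            fit_oplsda(x, labels, n_predictive=1, n_orthogonal=0)


class TestCrossValidation:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(["a", "b"], 20)
        x = rng.standard_normal((40, 15))
        x[labels == "b"] += 5.0
        acc, confusion = cross_validate(x, labels, 1, 0, folds=5, seed=0)
        assert acc == 1.0
        assert confusion.loc["a", "a"] == 20 and confusion.loc["b", "b"] == 20

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["a", "b"], 25)
        x = rng.standard_normal((50, 20))
        acc, _ = cross_validate(x, labels, 1, 0, folds=5, seed=1)
        assert 0.2 <= acc <= 0.8

    def test_same_seed_bit_stable(self):
        x, labels = three_class_data(seed=6)
        a1, c1 = cross_validate(x, labels, 2, 1, folds=5, seed=7)
        a2, c2 = cross_validate(x, labels, 2, 1, folds=5, seed=7)
        assert a1 == a2
        pd.testing.assert_frame_equal(c1, c2)

    def test_class_smaller_than_folds_rejected(self):
        x, labels = three_class_data(n_per=4)
        with pytest.raises(EquiscreenError, match="folds"):
            cross_validate(x, labels, 1, 0, folds=5)

    def test_component_scan_returns_series(self):
        x, labels = three_class_data(seed=8)
        scan = accuracy_by_components(x, labels, max_predictive=2, folds=4, seed=0)
        assert list(scan.index) == [1, 2]
        assert ((0 <= scan) & (scan <= 1)).all()


class TestPermutation:
    def test_strong_effect_gives_minimal_p(self):
        rng = np.random.default_rng(9)
        labels = np.repeat(["a", "b"], 12)
        x = rng.standard_normal((24, 10))
        x[labels == "b"] += 4.0
        res = permutation_test(x, labels, 1, 0, m=99, folds=4, seed=2)
        assert res.b == 0
        assert res.p == pytest.approx(1 / 100)

    def test_p_formula_and_bounds(self):
        rng = np.random.default_rng(10)
        labels = np.repeat(["a", "b"], 10)
        x = rng.standard_normal((20, 5))
        res = permutation_test(x, labels, 1, 0, m=49, folds=4, seed=3)
        assert res.p == (res.b + 1) / (res.m + 1)
        assert 1 / (res.m + 1) <= res.p <= 1


class TestLoadings:
    def test_peak_equal_to_score_has_unit_correlation(self):
        x, labels = three_class_data(seed=11)
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=0)
        x2 = np.column_stack([x, model.t[:, 0]])
        loadings = correlation_loadings(model, x2)
        assert loadings["tp1"].iloc[-1] == pytest.approx(1.0, abs=1e-10)
        assert ((loadings["tp1"].dropna() >= -1) & (loadings["tp1"].dropna() <= 1)).all()

    def test_zero_variance_peak_reported_missing(self):
        x, labels = three_class_data(seed=12)
        x[:, 5] = 2.0
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=0)
        loadings = correlation_loadings(model, x)
        assert np.isnan(loadings["tp1"].iloc[5])

    def test_planted_peaks_rank_top_decile(self):
        x, labels, _ = two_class_batch_data(seed=13)
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=1)
        loadings = correlation_loadings(model, x)["tp1"].abs()
        top = set(loadings.sort_values(ascending=False).head(50).index)
        assert len(top & set(range(10))) >= 8


class TestConcordance:
    def test_identical_and_reversed(self):
        rng = np.random.default_rng(14)
        a = pd.Series(rng.standard_normal(50), index=[f"m{i}" for i in range(50)])
        rho, p = loading_concordance(a, a)
        assert rho == pytest.approx(1.0)
        assert p < 1e-10
        rho_rev, _ = loading_concordance(a, pd.Series(-a, index=a.index))
        assert rho_rev == pytest.approx(-1.0)

    def test_too_few_shared_keys(self):
        a = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.raises(EquiscreenError, match=">=5"):
            loading_concordance(a, a)

    def test_independent_loadings_near_zero(self):
        rng = np.random.default_rng(15)
        idx = [f"m{i}" for i in range(104)]
        hits = 0
        for _ in range(40):
            a = pd.Series(rng.standard_normal(104), index=idx)
            b = pd.Series(rng.standard_normal(104), index=idx)
            rho, _ = loading_concordance(a, b)
            hits += abs(rho) < 0.2
        assert hits / 40 >= 0.90
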