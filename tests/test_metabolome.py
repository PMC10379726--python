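import numpy as np
import pandas as pd
import pytest

from fctpath.metabolome import (PLSModel, baseline_shift_tests,
                                bile_acid_ratios, fit_pls, p_corr,
                                select_discriminant, validate_pls, vip)
from fctpath.tables import SampleTable


def random_pls_data(rng, n=60, p=12, m=2, noise=0.3):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + noise * rng.normal(size=(n, m))
    return X, Y


class TestFitPLS:
    def test_y_equal_to_x_column_fully_explained(self, rng):
        # centered orthogonal X: the first weight vector is e1, so one
        # component reproduces Y exactly
        A = rng.normal(size=(40, 5))
        X, _ = np.linalg.qr(A - A.mean(axis=0))
        model = fit_pls(X, X[:, 0], n_components=1)
        assert model.explained_y_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_fit_explains_linear_y(self, rng):
        X = rng.normal(size=(40, 5))
        model = fit_pls(X, X[:, 0], n_components=5)
        assert model.r2y == pytest.approx(1.0, abs=1e-9)

    def test_first_weights_proportional_to_xty(self, rng):
        # orthonormal X columns: NIPALS first weight vector is X'Y direction
        q, _ = np.linalg.qr(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        model = fit_pls(q, y, n_components=1, scaling="none")
        Xc = q - q.mean(axis=0)
        yc = (y - y.mean()) / y.std(ddof=1)
        direction = Xc.T @ yc
        direction /= np.linalg.norm(direction)
        w = model.x_weights[:, 0]
        assert np.abs(w @ direction) == pytest.approx(1.0, abs=1e-6)

    def test_svd_oracle_first_component(self, rng):
        # univariate Y: first weight equals the leading left singular
        # vector of X'Y (here a single column, so X'Y normalized)
        X, Y = random_pls_data(rng, m=1)
        model = fit_pls(X, Y, n_components=1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        u = (Xs.T @ Ys).ravel()
        u /= np.linalg.norm(u)
        assert np.abs(model.x_weights[:, 0] @ u) == pytest.approx(1.0, abs=1e-8)

    def test_row_permutation_invariance(self, rng):
        X, Y = random_pls_data(rng)
        m1 = fit_pls(X, Y, n_components=2)
        perm = rng.permutation(X.shape[0])
        m2 = fit_pls(X[perm], Y[perm], n_components=2)
        assert np.allclose(m1.x_weights, m2.x_weights, atol=1e-8)
        assert np.allclose(m1.x_scores[perm], m2.x_scores, atol=1e-8)

    def test_constant_column_dropped_with_warning(self, rng):
        X, Y = random_pls_data(rng, p=5)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_pls(X, Y, n_components=1,
                            feature_ids=list("abcde"))
        assert model.feature_ids == ["a", "b", "d", "e"]

    def test_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, Y = random_pls_data(rng)
        model = fit_pls(X, Y, n_components=2)
        sk = PLSRegression(n_components=2, scale=True).fit(X, Y)
        for a in range(2):
            cos = np.abs(model.x_weights[:, a] @ sk.x_weights_[:, a])
            assert cos == pytest.approx(1.0, abs=1e-6)


class TestVIP:
    def test_sum_of_squares_identity(self, rng):
        for _ in range(5):
            X, Y = random_pls_data(rng, p=int(rng.integers(4, 20)))
            model = fit_pls(X, Y, n_components=3)
            v = vip(model)
            assert (v**2).sum() == pytest.approx(len(v), abs=1e-8)

    def test_equal_weights_give_unit_vip(self):
        model = PLSModel(
            n_components=1, x_scores=np.ones((4, 1)),
            x_weights=np.array([[0.7071], [-0.7071]]),
            x_loadings=np.ones((2, 1)), y_loadings=np.ones((1, 1)),
            explained_y_variance=np.array([0.5]),
            x_mean=np.zeros(2), x_scale=np.ones(2),
            y_mean=np.zeros(1), y_scale=np.ones(1),
            scaling="unit_variance", feature_ids=["a", "b"],
            kept_columns=np.arange(2))
        assert vip(model).tolist() == pytest.approx([1.0, 1.0])

    def test_zero_weight_variable_zero_vip(self):
        model = PLSModel(
            n_components=1, x_scores=np.ones((4, 1)),
            x_weights=np.array([[1.0], [0.0]]),
            x_loadings=np.ones((2, 1)), y_loadings=np.ones((1, 1)),
            explained_y_variance=np.array([0.4]),
            x_mean=np.zeros(2), x_scale=np.ones(2),
            y_mean=np.zeros(1), y_scale=np.ones(1),
            scaling="unit_variance", feature_ids=["a", "b"],
            kept_columns=np.arange(2))
        assert vip(model)["b"] == 0.0


class TestPCorr:
    def test_column_equal_to_scores(self, rng):
        X, Y = random_pls_data(rng, p=6)
        model = fit_pls(X, Y, n_components=2)
        # reconstruct an X whose 0th column is the component-2 score vector
        X2 = X.copy()
        X2[:, 0] = model.x_scores[:, 1]
        pc = p_corr(model, X2, component=2)
        assert pc.iloc[0] == pytest.approx(1.0, abs=1e-9)
        X2[:, 0] *= -1
        assert p_corr(model, X2, component=2).iloc[0] == pytest.approx(-1.0)

    def test_independent_columns_rarely_exceed_threshold(self, rng):
        n, p = 200, 300
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = fit_pls(X[:, :2], y, n_components=1)
        # correlate the scores against independent noise columns
        t = model.x_scores[:, 0]
        r = np.array([np.corrcoef(t, X[:, j])[0, 1] for j in range(2, p)])
        assert (np.abs(r) < 0.2).mean() >= 0.95


class TestValidatePLS:
    def test_noiseless_linear_high_q2(self, rng):
        X, Y = random_pls_data(rng, n=120, p=8, noise=0.0)
        q2, _ = validate_pls(X, Y, n_components=8, n_permutations=0, seed=0)
        assert q2 > 0.9

    def test_q2_below_r2(self, rng):
        X, Y = random_pls_data(rng, n=50, noise=1.0)
        model = fit_pls(X, Y, n_components=2)
        q2, _ = validate_pls(X, Y, n_components=2, n_permutations=0, seed=0)
        assert q2 <= model.r2y

    def test_permutation_p_bounds_and_null(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)  # independent of X
        q2, p = validate_pls(X, y, n_components=1, n_permutations=39, seed=1)
        assert 1 / 40 <= p <= 1.0
        assert p > 0.05  # null Y should not look predictive

    def test_signal_beats_permutations(self, rng):
        X, Y = random_pls_data(rng, n=60, noise=0.2)
        _, p = validate_pls(X, Y, n_components=2, n_permutations=19, seed=2)
        assert p == 1 / 20


class TestSelectDiscriminant:
    def test_reported_hmo_row_selected(self):
        # the flagship supplementation marker: VIP 1.63, p(corr) 0.52, p 1e-4
        out = select_discriminant(pd.Series({"2'-FL": 1.63}),
                                  pd.Series({"2'-FL": 0.52}),
                                  pd.Series({"2'-FL": 0.0001}))
        assert bool(out.loc["2'-FL", "selected"])

    @pytest.mark.parametrize("v,c,p,expected", [
        (0.99, 0.9, 0.001, False),   # VIP fails
        (1.5, 0.1, 0.001, False),    # |p(corr)| fails
        (1.5, -0.5, 0.2, False),     # WMW fails
        (1.01, -0.21, 0.049, True),  # all three barely pass
    ])
    def test_rule_conjunction(self, v, c, p, expected):
        out = select_discriminant(pd.Series({"m": v}), pd.Series({"m": c}),
                                  pd.Series({"m": p}))
        assert bool(out.loc["m", "selected"]) is expected

    def test_missing_statistic_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = select_discriminant(pd.Series({"a": 1.5, "b": 1.5}),
                                      pd.Series({"a": 0.5}),
                                      pd.Series({"a": 0.01, "b": 0.01}))
        assert list(out.index) == ["a"]

    def test_sorted_by_vip(self):
        out = select_discriminant(
            pd.Series({"a": 1.1, "b": 2.0, "c": 0.5}),
            pd.Series({"a": 0.3, "b": 0.3, "c": 0.3}),
            pd.Series({"a": 0.01, "b": 0.01, "c": 0.01}))
        assert list(out.index) == ["b", "a", "c"]


class TestBileAcidRatios:
    CONJ = ["TCA", "TCDCA", "TDCA", "GCA", "TLCA", "GCDCA", "GDCA", "GLCA"]

    def _panel(self, **values):
        cols = {c: [1.0] for c in self.CONJ}
        cols.update({"CA": [0.0], "CDCA": [0.0], "LCA": [0.0], "DCA": [0.0]})
        cols.update({k: [float(v)] for k, v in values.items()})
        return pd.DataFrame(cols, index=["s1"])

    def test_all_unconjugated_zero(self):
        r = bile_acid_ratios(self._panel()).iloc[0]
        assert (r == 0).all()

    def test_hand_worked_total_ratio(self):
        r = bile_acid_ratios(self._panel(CA=2, CDCA=1, LCA=1, DCA=0)).iloc[0]
        assert r["ba_cba"] == pytest.approx(4 / 7)
        assert r["ca_cca"] == pytest.approx(2 / 2)
        assert r["cdca_ccdca"] == pytest.approx(1 / 2)
        assert r["lca_clca"] == pytest.approx(1 / 2)

    def test_zero_conjugated_denominator_undefined(self):
        panel = self._panel(CA=2)
        panel[self.CONJ] = 0.0
        r = bile_acid_ratios(panel).iloc[0]
        assert np.isnan(r["ba_cba"]) and np.isnan(r["ca_cca"])

    def test_missing_analyte_flagged_undefined(self):
        panel = self._panel().drop(columns=["GLCA"])
        with pytest.warns(UserWarning, match="lca_clca"):
            r = bile_acid_ratios(panel).iloc[0]
        assert np.isnan(r["lca_clca"])
        assert np.isfinite(r["ba_cba"])  # GLCA not in the total-ratio sums


class TestBaselineShifts:
    def _metadata(self, visits, arm="control"):
        rows = [{"sample_id": f"s{i}", "infant_id": f"i{i}", "visit": v,
                 "age": 30 * (1 + "V0 V1 V3 V6".split().index(v)),
                 "arm": arm, "stratum": "EE"}
                for i, v in enumerate(visits)]
        return SampleTable(pd.DataFrame(rows))

    def test_constant_values_give_p_one(self):
        visits = ["V0"] * 6 + ["V1"] * 6 + ["V3"] * 6 + ["V6"] * 6
        meta = self._metadata(visits)
        values = pd.Series(1.0, index=[f"s{i}" for i in range(24)])
        ps = baseline_shift_tests(values, meta, "control")
        assert (ps == 1.0).all()

    def test_shift_at_v1_detected(self, rng):
        visits = ["V0"] * 15 + ["V1"] * 15 + ["V3"] * 15 + ["V6"] * 15
        meta = self._metadata(visits)
        vals = rng.normal(10, 1, size=60)
        vals[15:30] -= 5.0  # downward shift at V1 only
        ps = baseline_shift_tests(pd.Series(vals, index=[f"s{i}" for i in range(60)]),
                                  meta, "control")
        assert ps["V1"] == ps.min()
        assert ps["V1"] < 0.01

    def test_missing_visit_skipped_with_warning(self):
        meta = self._metadata(["V0", "V0", "V1", "V1"])
        values = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=["s0", "s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="V3"):
            ps = baseline_shift_tests(values, meta, "control")
        assert set(ps.index) == {"V1"}
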