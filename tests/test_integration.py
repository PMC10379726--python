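import numpy as np
import pandas as pd
import pytest

from fctpath.integration import (cluster_heatmap_order,
                                 fct_ordinal_association,
                                 interdomain_matrix, kendall_tau,
                                 treatment_association)
from fctpath.stats import cliffs_delta


def tau_b_oracle(x, y):
    """O(n^2) concordance count with tie corrections."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            if sx == 0 and sy == 0:
                continue
            if sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else 0.0


class TestKendall:
    def test_perfect_agreement(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_worked_two_thirds(self):
        # 5 concordant, 1 discordant of 6 pairs
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2 / 3)

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 51))
            x = rng.integers(0, 8, n).astype(float)   # ties present
            y = rng.normal(size=n)
            tau, p = kendall_tau(x, y)
            assert tau == pytest.approx(tau_b_oracle(x, y), abs=1e-10)
            assert 0 <= p <= 1

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            tau, p = kendall_tau([1.0, 1.0, 1.0], [1, 2, 3])
        assert (tau, p) == (0.0, 1.0)


class TestInterdomainMatrix:
    def _tables(self, rng, n=30):
        ko = pd.DataFrame(rng.random((n, 4)), columns=[f"K{i}" for i in range(4)],
                          index=[f"s{i}" for i in range(n)])
        mtb = pd.DataFrame(rng.random((n, 5)), columns=[f"m{i}" for i in range(5)],
                           index=[f"s{i}" for i in range(n)])
        return ko, mtb

    def test_detection_filter_excludes_sparse_features(self, rng):
        ko, mtb = self._tables(rng)
        mtb["rare"] = 0.0
        mtb.iloc[:2, mtb.columns.get_loc("rare")] = 1.0  # detected in 2 < 3
        with pytest.warns(UserWarning, match="filtered"):
            corr = interdomain_matrix(ko, mtb, min_detect=3)
        assert "rare" not in corr.tau.columns

    def test_identical_column_perfectly_correlated(self, rng):
        ko, mtb = self._tables(rng)
        mtb["twin"] = ko["K0"]
        corr = interdomain_matrix(ko, mtb)
        assert corr.tau.loc["K0", "twin"] == pytest.approx(1.0)
        assert corr.significant.loc["K0", "twin"]

    def test_bh_spans_whole_matrix(self, rng):
        from fctpath.stats import bh_adjust

        ko, mtb = self._tables(rng)
        corr = interdomain_matrix(ko, mtb)
        manual = bh_adjust(corr.p.to_numpy().ravel()).reshape(corr.p.shape)
        assert np.allclose(corr.q.to_numpy(), manual)
        # a filtered-out feature must not enter the correction
        mtb["rare"] = 0.0
        mtb.iloc[:1, mtb.columns.get_loc("rare")] = 1.0
        with pytest.warns(UserWarning):
            corr2 = interdomain_matrix(ko, mtb)
        pd.testing.assert_frame_equal(corr.q, corr2.q)

    def test_no_overlap_rejected(self, rng):
        ko, mtb = self._tables(rng)
        mtb.index = [f"t{i}" for i in range(len(mtb))]
        with pytest.raises(ValueError, match="overlapping"):
            interdomain_matrix(ko, mtb)

    def test_null_matrix_fdr_controlled(self, rng):
        # independent noise: on average the significant fraction stays small
        fracs = []
        for _ in range(10):
            ko = pd.DataFrame(rng.normal(size=(70, 10)) + 5,
                              index=[f"s{i}" for i in range(70)])
            ko.columns = [f"K{i}" for i in range(10)]
            mtb = pd.DataFrame(rng.normal(size=(70, 10)) + 5,
                               index=[f"s{i}" for i in range(70)])
            mtb.columns = [f"m{i}" for i in range(10)]
            corr = interdomain_matrix(ko, mtb)
            fracs.append(corr.significant.to_numpy().mean())
        assert np.mean(fracs) <= 0.10


class TestTreatmentAssociation:
    def test_constant_feature_null(self, rng):
        n = 24
        feats = pd.DataFrame({"flat": np.ones(n), "vary": rng.random(n)},
                             index=[f"s{i}" for i in range(n)])
        arms = pd.Series(["control", "test"] * (n // 2), index=feats.index)
        visits = pd.Series(["V3"] * n, index=feats.index)
        out = treatment_association(feats, arms, visits, "V3").set_index("feature_id")
        assert out.loc["flat", "p_value"] == 1.0
        assert out.loc["flat", "delta"] == 0.0

    def test_missing_visit_rejected(self, rng):
        feats = pd.DataFrame({"a": rng.random(4)}, index=list("wxyz"))
        arms = pd.Series(["control", "test"] * 2, index=feats.index)
        visits = pd.Series(["V3"] * 4, index=feats.index)
        with pytest.raises(ValueError, match="V6"):
            treatment_association(feats, arms, visits, "V6")


class TestFCTOrdinal:
    def test_monotone_feature_positive_tau(self):
        fct = pd.Series([1, 1, 2, 2, 3, 3, 4, 5], index=[f"s{i}" for i in range(8)])
        feature = pd.Series([1.0, 1.2, 2.0, 2.1, 3.0, 3.3, 4.0, 5.5],
                            index=fct.index)
        tau, p = fct_ordinal_association(feature, fct)
        assert tau > 0.9

    def test_single_level_undefined(self):
        fct = pd.Series([2, 2, 2], index=["a", "b", "c"])
        feature = pd.Series([1.0, 2.0, 3.0], index=fct.index)
        with pytest.warns(UserWarning, match="single FCT"):
            assert fct_ordinal_association(feature, fct) == (0.0, 1.0)

    def test_two_level_fct_agrees_with_mwu_direction(self, rng):
        # with two FCT levels, tau-b reduces to a rank-biserial-type measure:
        # its sign must match the Cliff's delta direction between the groups
        for _ in range(10):
            fct = pd.Series(rng.choice([1, 2], size=40),
                            index=[f"s{i}" for i in range(40)])
            feature = pd.Series(rng.normal(size=40) + 0.8 * fct.to_numpy(),
                                index=fct.index)
            tau, _ = fct_ordinal_association(feature, fct)
            d, _, _ = cliffs_delta(feature[fct == 2], feature[fct == 1])
            assert np.sign(tau) == np.sign(d)

    def test_null_feature_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            fct = pd.Series(rng.choice([1, 2, 3, 4, 5], size=30),
                            index=[f"s{i}" for i in range(30)])
            feature = pd.Series(rng.normal(size=30), index=fct.index)
            ps.append(fct_ordinal_association(feature, fct)[1])
        rate = np.mean(np.array(ps) < 0.05)
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 200)


class TestHeatmapOrder:
    def test_identical_rows_adjacent(self):
        tau = pd.DataFrame([[0.9, 0.1, 0.5],
                            [0.0, 0.8, 0.3],
                            [0.9, 0.1, 0.5]],
                           index=["a", "b", "c"], columns=["x", "y", "z"])
        rows, _ = cluster_heatmap_order(tau)
        assert abs(rows.index("a") - rows.index("c")) == 1

    def test_planted_blocks_contiguous(self, rng):
        block = np.vstack([np.tile([0.8, 0.8, -0.6, -0.6], (4, 1)),
                           np.tile([-0.7, -0.7, 0.7, 0.7], (4, 1))])
        tau = pd.DataFrame(block + 0.05 * rng.normal(size=block.shape),
                           index=[f"r{i}" for i in range(8)],
                           columns=list("wxyz"))
        rows, cols = cluster_heatmap_order(tau)
        first_half = {f"r{i}" for i in range(4)}
        assert {r for r in rows[:4]} in ({f"r{i}" for i in range(4)},
                                         {f"r{i}" for i in range(4, 8)})
        assert set(cols[:2]) in ({"w", "x"}, {"y", "z"})

    def test_single_row_identity(self):
        tau = pd.DataFrame([[0.1, 0.2]], index=["only"], columns=["x", "y"])
        rows, cols = cluster_heatmap_order(tau)
        assert rows == ["only"]

    def test_row_permutation_same_clusters(self, rng):
        tau = pd.DataFrame(rng.normal(size=(6, 4)),
                           index=[f"r{i}" for i in range(6)],
                           columns=list("wxyz"))
        rows1, _ = cluster_heatmap_order(tau)
        perm = rng.permutation(6)
        rows2, _ = cluster_heatmap_order(tau.iloc[perm])
        assert set(rows1) == set(rows2)
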