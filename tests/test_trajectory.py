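import numpy as np
import pandas as pd
import pytest

from fctpath.dmm import FCTAssignment
from fctpath.tables import SampleTable
from fctpath.trajectory import (assign_age_group, build_transition_graph,
                                cox_binary, fct_event_table, km_curve)


def make_cohort(samples):
    """samples: list of (infant, visit, age, arm, fct)."""
    rows, labels = [], {}
    for i, (infant, visit, age, arm, fct) in enumerate(samples):
        sid = f"{infant}_{visit}"
        rows.append({"sample_id": sid, "infant_id": infant, "visit": visit,
                     "age": age, "arm": arm, "stratum": "EE"})
        labels[sid] = fct
    meta = SampleTable(pd.DataFrame(rows))
    assignment = FCTAssignment(labels=pd.Series(labels), renumbering={})
    return assignment, meta


def logrank_oracle(records):
    """Classical log-rank chi-square by direct 2x2 summation over event times."""
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(bool)
    g = (records["arm"] == sorted(records["arm"].unique())[1]).to_numpy()
    num = var = 0.0
    for u in np.unique(t[e]):
        at_risk = t >= u
        n, n1 = at_risk.sum(), (at_risk & g).sum()
        d = (e & (t == u)).sum()
        d1 = (e & (t == u) & g).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num**2 / var


class TestAgeGroup:
    @pytest.mark.parametrize("age,month", [(0, 0), (44, 1), (75, 2),
                                           (15, 0), (16, 1), (365, 12)])
    def test_nearest_month_half_up(self, age, month):
        assert assign_age_group(age) == month

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_age_group(-1)


class TestTransitionGraph:
    def test_progression_edge_between_months(self):
        assignment, meta = make_cohort([("i1", "V0", 60, "control", 1),
                                        ("i1", "V1", 120, "control", 2)])
        g = build_transition_graph(assignment, meta)
        assert len(g.edges) == 1
        edge = g.edges.iloc[0]
        assert (edge.from_month, edge.to_month) == (2, 4)
        assert edge.category == "progression"

    def test_same_month_self_loop(self):
        assignment, meta = make_cohort([("i1", "V0", 50, "control", 2),
                                        ("i1", "V1", 70, "control", 2)])
        g = build_transition_graph(assignment, meta)
        edge = g.edges.iloc[0]
        assert edge.from_month == edge.to_month == 2
        assert edge.category == "no_change"

    def test_display_threshold_hides_but_retains(self):
        # 40 infants: 39 identical transitions and 1 rare one (fraction 0.025)
        samples = []
        for i in range(39):
            samples += [(f"a{i}", "V0", 60, "control", 1),
                        (f"a{i}", "V1", 120, "control", 2)]
        samples += [("rare", "V0", 60, "control", 1),
                    ("rare", "V1", 120, "control", 5)]
        assignment, meta = make_cohort(samples)
        g = build_transition_graph(assignment, meta, display_threshold=0.04)
        rare = g.edges[g.edges["to_fct"] == 5].iloc[0]
        assert rare.fraction == pytest.approx(1 / 40)
        assert rare.hidden
        assert not g.edges[g.edges["to_fct"] == 2].iloc[0].hidden
        assert "FCT5" not in g.to_dot().split("->", 1)[-1]

    def test_occupancy_columns_sum_to_one(self, default_cohort):
        assignment = FCTAssignment(labels=default_cohort.truth_fct,
                                   renumbering={})
        g = build_transition_graph(assignment, default_cohort.metadata)
        sums = g.nodes.groupby("age_month")["occupancy"].sum()
        assert np.allclose(sums, 1.0)
        # threshold only affects rendering flags, never occupancies
        g2 = build_transition_graph(assignment, default_cohort.metadata,
                                    display_threshold=0.0)
        pd.testing.assert_frame_equal(g.nodes, g2.nodes)

    def test_single_sample_infant_contributes_no_edges(self):
        assignment, meta = make_cohort([("solo", "V6", 365, "control", 4)])
        g = build_transition_graph(assignment, meta)
        assert len(g.edges) == 0
        assert len(g.nodes) == 1


class TestEventTable:
    def test_later_fct_counts_as_event(self):
        assignment, meta = make_cohort([("i1", "V0", 60, "test", 1),
                                        ("i1", "V1", 120, "test", 2),
                                        ("i1", "V3", 240, "test", 4)])
        rec = fct_event_table(assignment, meta, target_fct=3)
        assert rec.iloc[0]["event"] and rec.iloc[0]["time"] == 240

    def test_never_reached_censored_at_last_visit(self):
        assignment, meta = make_cohort([("i1", "V0", 60, "test", 1),
                                        ("i1", "V1", 120, "test", 2),
                                        ("i1", "V3", 240, "test", 2)])
        rec = fct_event_table(assignment, meta, target_fct=3)
        assert not rec.iloc[0]["event"] and rec.iloc[0]["time"] == 240

    def test_event_at_first_visit(self):
        assignment, meta = make_cohort([("i1", "V0", 90, "test", 3),
                                        ("i1", "V1", 120, "test", 3)])
        rec = fct_event_table(assignment, meta, target_fct=3)
        assert rec.iloc[0]["event"] and rec.iloc[0]["time"] == 90

    def test_single_sample_infants_excluded_with_warning(self):
        assignment, meta = make_cohort([("solo", "V6", 365, "test", 4),
                                        ("i1", "V0", 60, "test", 1),
                                        ("i1", "V1", 120, "test", 3)])
        with pytest.warns(UserWarning, match="excluded 1"):
            rec = fct_event_table(assignment, meta, target_fct=3)
        assert rec["infant_id"].tolist() == ["i1"]


class TestKaplanMeier:
    def test_all_censored_flat_one(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": False})
        assert (km_curve(rec)["survival"] == 1.0).all()

    def test_three_events_product_limit(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": True})
        km = km_curve(rec)
        assert km["survival"].tolist() == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])

    def test_non_increasing_from_one(self, rng):
        rec = pd.DataFrame({"time": rng.exponential(10, 40) + 0.1,
                            "event": rng.random(40) < 0.7})
        km = km_curve(rec)
        assert km["survival"].iloc[0] == 1.0
        assert (np.diff(km["survival"]) <= 1e-12).all()


class TestCox:
    def test_identical_groups_null(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3],
                            "event": [True] * 6,
                            "arm": ["control"] * 3 + ["test"] * 3})
        res = cox_binary(rec)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.score_chi2 == pytest.approx(0.0, abs=1e-12)

    def test_score_equals_logrank_hand_case(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 4], "event": [True] * 4,
                            "arm": ["a", "a", "b", "b"]})
        res = cox_binary(rec)
        assert res.score_chi2 == pytest.approx(logrank_oracle(rec))

    def test_score_equals_logrank_random_instances(self, rng):
        # tie-free instances: Cox score test == classical log-rank statistic
        for _ in range(25):
            n = int(rng.integers(6, 30))
            rec = pd.DataFrame({
                "time": rng.exponential(5, n) + 0.01,
                "event": rng.random(n) < 0.8,
                "arm": rng.choice(["a", "b"], n),
            })
            if rec.groupby("arm")["event"].sum().min() < 1 or rec["arm"].nunique() < 2:
                continue
            res = cox_binary(rec)
            assert res.score_chi2 == pytest.approx(logrank_oracle(rec), rel=1e-8)

    def test_hazard_ratio_consistency(self, rng):
        # true HR 0.5, exponential survival, censoring at a fixed horizon
        n = 500
        t0 = rng.exponential(1.0, n)
        t1 = rng.exponential(2.0, n)  # hazard halved
        cens = 2.5
        rec = pd.DataFrame({
            "time": np.concatenate([np.minimum(t0, cens), np.minimum(t1, cens)]),
            "event": np.concatenate([t0 <= cens, t1 <= cens]),
            "arm": ["control"] * n + ["test"] * n,
        })
        res = cox_binary(rec)
        assert 0.4 <= res.hazard_ratio <= 0.62
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        rec = pd.DataFrame({
            "time": rng.exponential(3, n) + 0.01,
            "event": rng.random(n) < 0.75,
            "arm": rng.choice(["control", "test"], n),
        })
        res = cox_binary(rec)
        df = rec.assign(z=(rec["arm"] == "test").astype(float)).drop(columns="arm")
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        assert res.beta == pytest.approx(cph.params_["z"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["z"], abs=1e-4)

    def test_no_events_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": False,
                            "arm": ["a", "b"]})
        with pytest.raises(ValueError, match="no events"):
            cox_binary(rec)

    def test_complete_separation_capped(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 10, 11, 12],
                            "event": [True, True, True, False, False, False],
                            "arm": ["b", "b", "b", "a", "a", "a"]})
        with pytest.warns(UserWarning, match="separation"):
            res = cox_binary(rec)
        assert res.meta["capped"]

    def test_logrank_type_one_error_calibrated(self, rng):
        # null generator: rejection rate at alpha = 0.05 within binomial CI
        reps, n = 1000, 30
        rejections = 0
        for _ in range(reps):
            rec = pd.DataFrame({
                "time": rng.exponential(1.0, 2 * n),
                "event": rng.random(2 * n) < 0.8,
                "arm": ["a"] * n + ["b"] * n,
            })
            if cox_binary(rec).score_p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)
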