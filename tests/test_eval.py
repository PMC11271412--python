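"""Survival metrics against brute-force, hand-computed and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from milsurv.evaluate import (
    aggregate_patient_risk,
    assign_risk_groups,
    concordance,
    cox_fit,
    cox_loglik,
    cumulative_auc_and_brier,
    interaction_test,
    km_estimate,
    logrank_test,
)


def concordance_brute(scores, time, event, tau=10.0):
    """Plain double-loop oracle with the same comparability rule."""
    t = np.minimum(time, tau)
    e = event * (time <= tau)
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if e[i] == 1 and t[i] < t[j]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_and_inverted_ranking(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.ones(3, int)
        assert concordance([3, 2, 1], t, e) == 1.0
        assert concordance([1, 2, 3], t, e) == 0.0

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(50):
            n = 15
            scores = rng.standard_normal(n)
            time = rng.exponential(5.0, n)
            event = rng.integers(0, 2, n)
            if (event * (time <= 10)).sum() == 0:
                continue
            assert concordance(scores, time, event) == pytest.approx(
                concordance_brute(scores, time, event), abs=1e-12
            )

    def test_tied_scores_count_half(self):
        c = concordance([1.0, 1.0], [1.0, 2.0], [1, 1])
        assert c == 0.5

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance([1.0, 2.0], [5.0, 5.0], [0, 0])

    def test_agrees_with_sksurv_when_untruncated(self, rng):
        from sksurv.metrics import concordance_index_censored

        n = 40
        scores = rng.standard_normal(n)
        time = rng.exponential(3.0, n) + rng.uniform(0, 1e-6, n)  # no ties
        event = rng.integers(0, 2, n).astype(bool)
        event[:5] = True
        ours = concordance(scores, time, event.astype(int), tau=np.inf)
        theirs = concordance_index_censored(event, time, scores)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0))
    def test_invariant_under_strictly_increasing_transform(self, a, b):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(20)
        time = rng.exponential(4.0, 20)
        event = rng.integers(0, 2, 20)
        event[0] = 1
        base = concordance(scores, time, event)
        assert concordance(a * scores + b, time, event) == pytest.approx(base)

    def test_uno_variant_runs_and_is_bounded(self, rng):
        n = 60
        scores = rng.standard_normal(n)
        time = rng.exponential(5.0, n)
        event = rng.integers(0, 2, n)
        event[:10] = 1
        c = concordance(scores, time, event, tau=8.0, method="uno")
        assert 0.0 <= c <= 1.0


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_all_events_product_limit_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        steps = km.set_index("time")["survival"]
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_censored_ten_record_fixture_matches_hand_table(self):
        time = [1, 2, 3, 4, 4, 5, 6, 7, 8, 9]
        event = [1, 0, 1, 1, 0, 1, 0, 1, 0, 1]
        km = km_estimate(time, event)
        # hand product-limit: at-risk/deaths per event time
        # t=1: 10 at risk, 1 death -> 9/10
        # t=3: 8 at risk, 1 death  -> 9/10 * 7/8
        # t=4: 7 at risk, 1 death  -> ... * 6/7
        # t=5: 5 at risk, 1 death  -> ... * 4/5
        # t=7: 3 at risk, 1 death  -> ... * 2/3
        # t=9: 1 at risk, 1 death  -> 0
        expect = {}
        s = 1.0
        for t, (r, d) in {1: (10, 1), 3: (8, 1), 4: (7, 1), 5: (5, 1),
                          7: (3, 1), 9: (1, 1)}.items():
            s *= (r - d) / r
            expect[t] = s
        steps = km.set_index("time")["survival"]
        for t, v in expect.items():
            assert steps[float(t)] == pytest.approx(v, abs=1e-12)

    def test_uncensored_equals_empirical_survival(self, rng):
        t = np.sort(rng.exponential(2.0, 30))
        km = km_estimate(t, np.ones(30, int))
        emp = 1.0 - np.searchsorted(t, km["time"], side="right") / 30
        np.testing.assert_allclose(km["survival"], emp, atol=1e-12)

    def test_confidence_band_contains_estimate(self):
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        inner = km.iloc[:-1]  # the band collapses once S hits 0
        assert (inner["ci_lower"] <= inner["survival"] + 1e-12).all()
        assert (inner["ci_upper"] >= inner["survival"] - 1e-12).all()


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0] * 4 + [1] * 4
        chi2, p = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_two_group_hand_computed_statistic(self):
        # complete separation: group A events at 1,2,3; B events at 4,5,6
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        groups = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(time, event, groups)
        # hand 2x2 tables at each event time (O-E for group 0):
        # t=1: E=3/6, t=2: E=2/5, t=3: E=1/4 -> O-E = 3 - 1.15 = 1.85
        # variances: hypergeometric var at each time
        o_minus_e = 3 - (3 / 6 + 2 / 5 + 1 / 4)
        var = (3 * 3) / 36 + (2 * 3) / 25 + (1 * 3) / 16
        assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-10)
        assert p < 0.05

    def test_label_swap_invariance(self, rng):
        time = rng.exponential(3.0, 30)
        event = rng.integers(0, 2, 30)
        event[:5] = 1
        groups = rng.integers(0, 2, 30)
        groups[:2] = [0, 1]
        _, p1 = logrank_test(time, event, groups)
        _, p2 = logrank_test(time, event, 1 - groups)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestRiskGroups:
    def test_cutoffs_from_1_to_100(self):
        groups, labels = assign_risk_groups(np.arange(1.0, 101.0))
        assert groups.c50 == pytest.approx(50.5)
        assert groups.c75 == pytest.approx(75.25)
        assert groups.label([60.0])[0] == "intermediate"

    def test_training_proportions_50_25_25(self, rng):
        scores = rng.standard_normal(200)
        _, labels = assign_risk_groups(scores)
        counts = {g: (labels == g).sum() for g in np.unique(labels)}
        assert abs(counts["low"] - 100) <= 1
        assert abs(counts["intermediate"] - 50) <= 1
        assert abs(counts["high"] - 50) <= 1

    def test_score_below_training_minimum_is_low(self, rng):
        groups, _ = assign_risk_groups(rng.standard_normal(50))
        assert groups.label([-100.0])[0] == "low"

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_risk_groups(np.ones(10))


class TestCoxFit:
    def test_matches_analytic_score_root_n3(self):
        # smallest non-degenerate fixture: the event subject's covariate is
        # interior to the risk-set range, so the score equation has a
        # finite root
        x = np.array([0.0, 0.7, 1.0])
        time = np.array([1.0, 0.5, 2.0])   # subject 1 (x=0.7) events first
        event = np.array([1, 1, 0])
        from scipy.optimize import brentq

        def score(beta):
            # independent analytic score: two event terms
            # event at t=0.5: risk set {0,1,2}; event at t=1: risk set {0,2}
            w = np.exp(beta * x)
            s1 = 0.7 - (x * w).sum() / w.sum()
            w2 = np.exp(beta * x[[0, 2]])
            s2 = 0.0 - (x[[0, 2]] * w2).sum() / w2.sum()
            return s1 + s2

        root = brentq(score, -50, 50, xtol=1e-12)
        res = cox_fit(pd.DataFrame({"x": x}), time, event)
        assert res.coef[0] == pytest.approx(root, abs=1e-6)

    def test_optimum_beats_random_draws(self, rng):
        n = 50
        x = pd.DataFrame({"a": rng.standard_normal(n),
                          "b": rng.standard_normal(n)})
        time = rng.exponential(2.0, n)
        event = rng.integers(0, 2, n)
        event[:10] = 1
        res = cox_fit(x, time, event)
        ll_hat = cox_loglik(res.coef, x, time, event)
        draws = rng.standard_normal((1000, 2)) * 2.0
        for beta in draws:
            assert ll_hat >= cox_loglik(beta, x, time, event) - 1e-9

    def test_agrees_with_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 60
        df = pd.DataFrame(
            {
                "a": rng.standard_normal(n),
                "b": rng.integers(0, 2, n).astype(float),
                "T": rng.exponential(2.0, n) + rng.uniform(0, 1e-9, n),
                "E": rng.integers(0, 2, n),
            }
        )
        df.loc[:10, "E"] = 1
        res = cox_fit(df[["a", "b"]], df["T"], df["E"])
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(res.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.se, cph.standard_errors_.to_numpy(),
                                   atol=1e-5)

    def test_duplicated_column_rejected(self, rng):
        x = rng.standard_normal(20)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError):
            cox_fit(df, np.arange(1, 21.0), np.ones(20, int))

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(ValueError):
            cox_fit(df, np.arange(1, 11.0), np.ones(10, int))

    def test_no_events_rejected(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(10)})
        with pytest.raises(ValueError):
            cox_fit(df, np.arange(1, 11.0), np.zeros(10, int))

    def test_separation_raises_diagnostic(self):
        # binary covariate perfectly ordered with event times
        df = pd.DataFrame({"a": [1.0, 1.0, 0.0, 0.0]})
        with pytest.raises(RuntimeError):
            cox_fit(df, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])

    def test_sanity_against_logrank_on_binary_covariate(self, rng):
        n = 80
        group = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / np.exp(1.2 * group))
        event = np.ones(n, int)
        res = cox_fit(pd.DataFrame({"g": group.astype(float)}), time, event)
        _, p_lr = logrank_test(time, event, group)
        assert (res.p[0] < 0.05) == (p_lr < 0.05)


class TestAucBrier:
    def fixture(self, rng, n=60):
        time = rng.exponential(5.0, n)
        event = np.ones(n, int)  # uncensored -> IPCW weights are 1
        return pd.DataFrame(
            {"patient_id": range(n), "time_years": time, "event": event,
             "mol_class": "NSMP", "stage": "I"}
        )

    def test_perfect_separation_auc_one(self, rng):
        rec = self.fixture(rng)
        t_eval = np.array([np.quantile(rec["time_years"], 0.5)])
        s = np.where(rec["time_years"] <= t_eval[0], 0.1, 0.9)[:, None]
        out = cumulative_auc_and_brier(s, rec, t_eval)
        assert out["auc"][0] == pytest.approx(1.0)

    def test_constant_half_prediction_brier_quarter(self, rng):
        rec = self.fixture(rng)
        t_eval = np.quantile(rec["time_years"], [0.3, 0.6]).astype(float)
        s = np.full((len(rec), 2), 0.5)
        out = cumulative_auc_and_brier(s, rec, t_eval)
        np.testing.assert_allclose(out["brier"], 0.25, atol=1e-12)
        assert out["integrated_brier"] == pytest.approx(0.25)

    def test_matches_direct_weighted_sums_when_uncensored(self, rng):
        rec = self.fixture(rng, n=40)
        t0 = float(np.quantile(rec["time_years"], 0.5))
        s = rng.uniform(0.1, 0.9, size=(40, 1))
        out = cumulative_auc_and_brier(s, rec, np.array([t0]))
        risk = 1.0 - s[:, 0]
        cases = rec["time_years"].to_numpy() <= t0
        # direct cumulative/dynamic AUC: P(risk_case > risk_control)
        num = den = 0.0
        for i in np.flatnonzero(cases):
            for j in np.flatnonzero(~cases):
                den += 1
                num += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
        assert out["auc"][0] == pytest.approx(num / den, abs=1e-10)
        brier = np.mean(
            np.where(cases, (0.0 - s[:, 0]) ** 2, (1.0 - s[:, 0]) ** 2)
        )
        assert out["brier"][0] == pytest.approx(brier, abs=1e-10)

    def test_all_censored_rejected(self, rng):
        rec = self.fixture(rng)
        rec["event"] = 0
        with pytest.raises(ValueError):
            cumulative_auc_and_brier(np.full((len(rec), 1), 0.5), rec,
                                     np.array([1.0]))


class TestInteraction:
    @staticmethod
    def records(rng, n=300, benefit_high=0.0):
        risk = rng.standard_normal(n)
        treat = rng.integers(0, 2, n)
        high = risk > np.quantile(risk, 0.75)
        rate = 0.2 * np.exp(risk + 0.0 * treat + benefit_high * treat * high)
        t = rng.exponential(1.0 / rate)
        c = rng.uniform(0, 12, n)
        rec = pd.DataFrame(
            {
                "patient_id": range(n),
                "time_years": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "treatment": treat,
            }
        )
        return rec, risk

    def test_treatment_relabel_symmetry(self, rng):
        rec, risk = self.records(rng)
        p1 = interaction_test(rec, risk)["p"]
        rec2 = rec.assign(treatment=1 - rec["treatment"])
        p2 = interaction_test(rec2, risk)["p"]
        assert p1 == pytest.approx(p2, abs=1e-6)

    def test_single_arm_rejected(self, rng):
        rec, risk = self.records(rng)
        rec["treatment"] = 1
        with pytest.raises(ValueError):
            interaction_test(rec, risk)

    def test_detects_strong_subgroup_benefit(self, rng):
        rec, risk = self.records(rng, n=2000, benefit_high=-1.5)
        out = interaction_test(rec, risk)
        assert out["p"] < 0.05
        assert out["coef"] < 0

    def test_categorical_mode_tests_high_group_product(self, rng):
        rec, risk = self.records(rng, n=600, benefit_high=-1.5)
        _, labels = assign_risk_groups(risk)
        out = interaction_test(rec, labels, categorical=True)
        assert out["term"] == "treatment_x_high"
        assert 0.0 <= out["p"] <= 1.0


class TestAggregate:
    def test_mean_and_median(self):
        df = pd.DataFrame({"patient_id": ["a"] * 3, "risk": [1.0, 2.0, 3.0]})
        assert aggregate_patient_risk(df, "mean")["a"] == 2.0
        assert aggregate_patient_risk(df, "median")["a"] == 2.0

    def test_single_slide_passthrough(self):
        df = pd.DataFrame({"patient_id": ["a"], "risk": [1.7]})
        assert aggregate_patient_risk(df)["a"] == 1.7

    def test_duplicated_slides_keep_score(self):
        df = pd.DataFrame({"patient_id": ["a"] * 4, "risk": [2.5] * 4})
        assert aggregate_patient_risk(df)["a"] == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient_risk(pd.DataFrame(columns=["patient_id", "risk"]))

    def test_multi_slide_cohort_aggregates_per_patient(self):
        """Slide-level risks from a multi-slide synthetic cohort reduce to
        one score per patient; merged-bag inference is the alternative."""
        from milsurv.bags import merge_bags
        from milsurv.model import Model, ModelConfig
        from milsurv.synthetic import SimConfig, generate_cohort, records_to_indices

        cfg = SimConfig(n_patients=6, slides_per_patient=(2, 3),
                        bag_size_range=(5, 8), feature_dim=8, seed=3)
        nested, records, _ = generate_cohort(cfg)
        model = Model(ModelConfig(in_dim=8, encoder_dims=(10, 6),
                                  attn_hidden=4, embed_dim=4, embed_out=3,
                                  fused_hidden=(8, 6), dropout=0.0, seed=3))
        mol, stage = records_to_indices(records)
        rows = []
        for i, patient_bags in enumerate(nested):
            for bag in patient_bags:
                risk = model.forward(bag.features.astype(float),
                                     int(mol[i]), int(stage[i])).risk
                rows.append((records["patient_id"].iloc[i], risk))
        slide_scores = pd.DataFrame(rows, columns=["patient_id", "risk"])
        per_patient = aggregate_patient_risk(slide_scores, "median")
        assert len(per_patient) == 6
        # merged-bag route also yields one finite risk per patient
        merged = merge_bags(nested[0])
        r = model.forward(merged.features.astype(float), int(mol[0]),
                          int(stage[0])).risk
        assert 0 < r < 4
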