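"""Validation metrics: concordance, paired bootstrap, screening curves,
post-test probability, reclassification, stratified evaluation, downsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protrisk import (
    OutcomeTable,
    bootstrap_compare,
    category_free_nri,
    downsample_cases,
    harrell_c,
    idi,
    post_test_probability,
    screening_curve,
    stratified_eval,
)
from tests.conftest import brute_force_harrell


def _outcomes(times, events, horizon=10.0) -> OutcomeTable:
    table = pd.DataFrame(
        {"time_years": times, "event": events, "prevalent": 0},
        index=pd.Index([f"S{i}" for i in range(len(times))], name="sample_id"),
    )
    return OutcomeTable(table, horizon_years=horizon)


class TestHarrellC:
    def test_perfect_ranking_gives_one(self):
        times = np.arange(1.0, 21.0)
        assert harrell_c(times, np.ones(20, int), -times) == 1.0

    def test_three_subject_example(self):
        # pairs: (1,2) disc, (1,3) conc, (2,3) disc -> wait, enumerate:
        # scores (3,1,2) on times (1,2,3): (1,2): 3>1 conc; (1,3): 3>2 conc;
        # (2,3): 1<2 disc -> C = 2/3
        assert harrell_c([1, 2, 3], [1, 1, 1], [3, 1, 2]) == pytest.approx(2 / 3)

    def test_random_score_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        times = rng.exponential(5, n)
        events = (rng.random(n) < 0.7).astype(int)
        c = harrell_c(times, events, rng.standard_normal(n))
        assert abs(c - 0.5) < 0.02

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_equals_brute_force_enumeration(self, seed):
        """Oracle equivalence on small instances with censoring and ties in
        both times and scores."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        times = rng.integers(1, 10, n).astype(float)  # ties likely
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        scores = rng.integers(0, 5, n).astype(float)
        try:
            got = harrell_c(times, events, scores)
        except ValueError:
            return  # no comparable pairs in this draw
        assert got == pytest.approx(brute_force_harrell(times, events, scores), abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [0, 0], [1, 2])


class TestBootstrapCompare:
    def test_self_comparison_delta_zero_ci_contains_zero(self):
        rng = np.random.default_rng(1)
        n = 300
        out = _outcomes(rng.exponential(5, n), (rng.random(n) < 0.5).astype(int))
        s = rng.standard_normal(n)
        _, _, delta = bootstrap_compare(s, s, out, B=200, seed=1)
        assert delta.delta_mean == 0.0
        assert delta.ci_low <= 0.0 <= delta.ci_high
        assert not delta.significant

    def test_informative_score_beats_random(self):
        rng = np.random.default_rng(2)
        n = 1000
        lp = rng.standard_normal(n)
        times = rng.exponential(np.exp(-lp))
        cut = np.quantile(times, 0.2)  # ~200 events
        events = (times <= cut).astype(int)
        times = np.minimum(times, cut)
        out = _outcomes(times, events)
        ra, rb, delta = bootstrap_compare(rng.standard_normal(n), lp, out, B=500, seed=2)
        assert delta.significant and delta.ci_low > 0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        n = 200
        out = _outcomes(rng.exponential(5, n), (rng.random(n) < 0.5).astype(int))
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        d1 = bootstrap_compare(a, b, out, B=100, seed=7)[2]
        d2 = bootstrap_compare(a, b, out, B=100, seed=7)[2]
        assert (d1.delta_mean, d1.ci_low, d1.ci_high) == (d2.delta_mean, d2.ci_low, d2.ci_high)


class TestScreeningCurve:
    def test_lr_equals_dr_over_fpr_at_every_grid_point(self):
        rng = np.random.default_rng(4)
        n = 2000
        times = np.where(rng.random(n) < 0.15, 5.0, 10.0)
        events = (times < 10).astype(int)
        out = _outcomes(times, events)
        curve = screening_curve(rng.standard_normal(n), out).table
        np.testing.assert_allclose(curve["lr"], curve["dr"] / curve["fpr"])
        # counts-level identities
        np.testing.assert_allclose(curve["fpr"], curve["FP"] / (curve["FP"] + curve["TN"]))
        np.testing.assert_allclose(curve["dr"], curve["TP"] / (curve["TP"] + curve["FN"]))

    def test_random_score_tracks_fpr(self):
        rng = np.random.default_rng(5)
        n = 6000
        times = np.where(rng.random(n) < 0.10, 5.0, 10.0)
        events = (times < 10).astype(int)
        out = _outcomes(times, events)
        curve = screening_curve(rng.standard_normal(n), out).table
        n_cases = int(events.sum())
        se = np.sqrt(curve["fpr"] * (1 - curve["fpr"]) / n_cases)
        assert ((curve["dr"] - curve["fpr"]).abs() <= 3 * se).all()

    def test_perfect_separation_detects_everything(self):
        n_cases, n_controls = 50, 500
        times = np.r_[np.full(n_cases, 4.0), np.full(n_controls, 10.0)]
        events = np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)]
        scores = np.r_[np.full(n_cases, 1e4), np.arange(n_controls, dtype=float)]
        curve = screening_curve(scores, _outcomes(times, events)).table
        assert (curve["dr"] == 1.0).all()

    def test_dr_monotone_in_fpr(self):
        rng = np.random.default_rng(6)
        n = 1000
        times = np.where(rng.random(n) < 0.2, 5.0, 10.0)
        events = (times < 10).astype(int)
        scores = rng.standard_normal(n) + events  # informative
        curve = screening_curve(scores, _outcomes(times, events)).table
        assert curve["dr"].is_monotonic_increasing

    def test_too_few_controls_rejected(self):
        times = np.r_[np.full(20, 5.0), np.full(5, 10.0)]
        events = np.r_[np.ones(20, int), np.zeros(5, int)]
        with pytest.raises(ValueError):
            screening_curve(np.arange(25.0), _outcomes(times, events))

    def test_five_year_horizon_by_argument_only(self):
        """Re-evaluating a 10-year model at 5 years only moves the
        case/control boundary."""
        times = np.r_[3.0, 7.0, np.full(20, 10.0)]
        events = np.r_[1, 1, np.zeros(20, int)]
        out = _outcomes(times, events)
        scores = np.r_[50.0, 40.0, np.arange(20, dtype=float)]
        ten = screening_curve(scores, out, horizon=10.0).table
        five = screening_curve(scores, out, horizon=5.0).table
        assert (ten["TP"] + ten["FN"]).iloc[0] == 2
        assert (five["TP"] + five["FN"]).iloc[0] == 1  # the 7-year case is no longer a 5-y case


class TestPostTestProbability:
    def test_uninformative_test_returns_pretest(self):
        assert post_test_probability(1.0, 0.3) == pytest.approx(0.3)

    def test_zero_lr_rules_out(self):
        assert post_test_probability(0.0, 0.3) == 0.0

    def test_odds_arithmetic(self):
        lr, pre = 8.08, 0.01
        odds = pre / (1 - pre)
        assert post_test_probability(lr, pre) == pytest.approx(lr * odds / (1 + lr * odds))
        assert post_test_probability(lr, pre) == pytest.approx(0.0755, abs=5e-5)

    def test_certain_pretest_rejected(self):
        with pytest.raises(ValueError):
            post_test_probability(2.0, 1.0)


def _risk_outcomes():
    # 10 evaluable subjects: 4 cases, 6 controls
    times = np.r_[np.full(4, 5.0), np.full(6, 10.0)]
    events = np.r_[np.ones(4, int), np.zeros(6, int)]
    return _outcomes(times, events)


class TestReclassification:
    def test_identity_is_zero(self):
        out = _risk_outcomes()
        r = np.linspace(0.05, 0.8, 10)
        assert category_free_nri(r, r, out) == 0.0
        assert idi(r, r, out) == 0.0

    def test_margin_larger_than_any_move_gives_zero_nri(self):
        out = _risk_outcomes()
        old = np.linspace(0.05, 0.8, 10)
        new = old + 0.05
        assert category_free_nri(old, new, out, margin=0.15) == 0.0

    def test_nri_matches_hand_enumeration(self):
        out = _risk_outcomes()
        old = np.array([0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10])
        new = np.array([0.30, 0.30, 0.10, 0.05, 0.30, 0.10, 0.10, 0.10, 0.10, 0.05])
        # cases (first 4): up 2, down 0 -> +2/4; controls: up 1, down 0 -> -1/6
        expected = 2 / 4 + (0 - 1) / 6
        assert category_free_nri(old, new, out, margin=0.15) == pytest.approx(expected)

    def test_case_only_shift_moves_idi_by_shift(self):
        out = _risk_outcomes()
        old = np.full(10, 0.2)
        new = old.copy()
        new[:4] += 0.1  # cases only
        assert idi(old, new, out) == pytest.approx(0.1)

    def test_idi_matches_hand_computation(self):
        times = np.r_[np.full(3, 5.0), np.full(5, 10.0)]
        events = np.r_[np.ones(3, int), np.zeros(5, int)]
        out = _outcomes(times, events)
        old = np.array([0.4, 0.3, 0.5, 0.2, 0.1, 0.3, 0.2, 0.2])
        new = np.array([0.6, 0.5, 0.4, 0.1, 0.2, 0.2, 0.3, 0.1])
        slope_new = new[:3].mean() - new[3:].mean()
        slope_old = old[:3].mean() - old[3:].mean()
        assert idi(old, new, out) == pytest.approx(slope_new - slope_old)

    def test_antisymmetric_under_model_swap(self):
        rng = np.random.default_rng(7)
        out = _risk_outcomes()
        old = rng.uniform(0, 1, 10)
        new = rng.uniform(0, 1, 10)
        assert category_free_nri(old, new, out) == pytest.approx(-category_free_nri(new, old, out))
        assert idi(old, new, out) == pytest.approx(-idi(new, old, out))

    def test_all_case_or_all_control_rejected(self):
        times = np.full(5, 5.0)
        events = np.ones(5, int)
        with pytest.raises(ValueError):
            idi(np.full(5, 0.1), np.full(5, 0.2), _outcomes(times, events))


class TestStratifiedEval:
    def _setup(self):
        rng = np.random.default_rng(8)
        n = 400
        times = rng.exponential(8, n).clip(max=10.0)
        events = ((times < 10) & (rng.random(n) < 0.8)).astype(int)
        out = _outcomes(times, events)
        strata = pd.Series(np.r_[["men"] * 350, ["women"] * 50], index=out.table.index)
        return out, strata, rng

    def test_small_stratum_skipped_with_reason(self):
        out, strata, rng = self._setup()
        # force few cases among women
        t = out.table.copy()
        t.loc[strata == "women", "event"] = 0
        t.loc[t.index[strata == "women"][:12], "event"] = 1
        t.loc[t.index[strata == "women"][:12], "time_years"] = 5.0
        out2 = OutcomeTable(t, 10.0)
        res = stratified_eval(rng.standard_normal(400), rng.standard_normal(400),
                              out2, strata, min_cases=20, B=100, seed=1)
        assert res["women"]["skipped"] and "12" in res["women"]["reason"]
        assert not res["men"]["skipped"]

    def test_all_strata_skipped_raises(self):
        out, strata, rng = self._setup()
        res_t = out.table.copy()
        res_t["event"] = 0
        res_t.loc[res_t.index[:5], "event"] = 1
        res_t.loc[res_t.index[:5], "time_years"] = 5.0
        with pytest.raises(ValueError):
            stratified_eval(rng.standard_normal(400), rng.standard_normal(400),
                            OutcomeTable(res_t, 10.0), strata, min_cases=20, B=50, seed=1)

    def test_deterministic_under_seed(self):
        out, strata, rng = self._setup()
        a = rng.standard_normal(400)
        b = rng.standard_normal(400)
        r1 = stratified_eval(a, b, out, strata, min_cases=20, B=100, seed=3)
        r2 = stratified_eval(a, b, out, strata, min_cases=20, B=100, seed=3)
        assert r1["men"]["delta"].delta_mean == r2["men"]["delta"].delta_mean


class TestDownsampleCases:
    def test_full_target_is_identity_up_to_order(self):
        out = _risk_outcomes()
        kept = downsample_cases(out, 4, seed=0)
        pd.testing.assert_frame_equal(kept.table, out.table)

    def test_exact_case_count_retained(self):
        rng = np.random.default_rng(9)
        n = 3000
        times = np.where(rng.random(n) < 0.3, 5.0, 10.0)
        events = (times < 10).astype(int)
        out = _outcomes(times, events)
        kept = downsample_cases(out, 80, seed=1)
        assert kept.n_incident_cases == 80
        assert (kept.table["event"] == 0).sum() == (events == 0).sum()

    def test_target_above_available_rejected(self):
        with pytest.raises(ValueError):
            downsample_cases(_risk_outcomes(), 100, seed=0)
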