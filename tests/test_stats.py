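"""Behavioral-statistics tests with independent closed-form/enumeration
oracles for the two-group tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import special

from volstop.engine import TaskConfig, run_experiment, run_session
from volstop.experiments import (mouse_summary_table, session_endpoint,
                                 summarize_and_compare)
from volstop.stats import (InsufficientDataError, StatsError,
                           UndefinedRateError, mann_whitney_u,
                           response_times, significance_stars, success_rate,
                           training_criterion, unpaired_t_test)
from volstop.synth import AgentParams, manipulation_mode


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pooled_t_oracle(a, b):
    """Textbook pooled-variance t and its two-tailed p (closed form)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * special.stdtr(df, -abs(t))
    return t, p


def _u_min(a, b):
    u_a = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return min(u_a, len(a) * len(b) - u_a)


def mw_exact_oracle(a, b):
    """Exact two-tailed Mann-Whitney p by enumerating every labeling."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = _u_min(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if _u_min(grp, rest) <= u_obs + 1e-12:
            count += 1
    return min(1.0, count / total)


# ---------------------------------------------------------------------------
# endpoint bookkeeping
# ---------------------------------------------------------------------------

class TestSuccessRate:
    def test_simple_fraction(self, profiles, control):
        cfg = TaskConfig(n_success_target=8, p_go=1.0)
        agent = AgentParams(p_go_success=0.8)
        log = run_session(agent, profiles, cfg, control, seed=3,
                          synth_traces=False)
        assert success_rate(log, "GO") == log.successes("GO") / log.presented("GO")

    def test_perfect_agent_rate_is_one(self, profiles, control):
        cfg = TaskConfig(n_success_target=10)
        agent = AgentParams(p_go_success=1.0, p_inhibit=1.0,
                            premature_rate=0.0)
        log = run_session(agent, profiles, cfg, control, seed=4,
                          synth_traces=False)
        assert success_rate(log, "GO") == 1.0
        assert success_rate(log, "NOGO") == 1.0

    def test_binomial_consistency(self, profiles, control):
        cfg = TaskConfig(n_success_target=140, p_go=1.0, max_trials=400)
        agent = AgentParams(p_go_success=0.7)
        pres = succ = 0
        for s in range(3):
            log = run_session(agent, profiles, cfg, control, seed=s,
                              synth_traces=False)
            pres += log.presented("GO")
            succ += log.successes("GO")
        se = math.sqrt(0.7 * 0.3 / pres)
        assert abs(succ / pres - 0.7) < 3 * se

    def test_zero_presented_rejected(self, profiles, control):
        cfg = TaskConfig(n_success_target=3, p_go=1.0)
        log = run_session(AgentParams(), profiles, cfg, control, seed=5,
                          synth_traces=False)
        with pytest.raises(UndefinedRateError):
            success_rate(log, "NOGO")


class TestResponseTimes:
    def test_successful_nogo_has_no_response_time(self, profiles, control):
        cfg = TaskConfig(n_success_target=10, p_go=0.0)
        agent = AgentParams(p_inhibit=1.0, premature_rate=0.0)
        log = run_session(agent, profiles, cfg, control, seed=6,
                          synth_traces=False)
        assert response_times(log, "NOGO", "success") == []

    def test_values_match_logged_crossings_exactly(self, behavior_session):
        log = behavior_session
        got = response_times(log, "GO", "success")
        expect = [dict(t.events)["crossing"] for t in log.trials
                  if t.trial_type == "GO" and t.outcome == "success"]
        assert got == expect
        gt_cross = [g["crossing"] for t, g in
                    zip(log.trials, log.ground_truth)
                    if t.trial_type == "GO" and t.outcome == "success"]
        assert got == gt_cross

    def test_invalid_filter_rejected(self, behavior_session):
        with pytest.raises(StatsError):
            response_times(behavior_session, "GO", "maybe")


class TestTrainingCriterion:
    @pytest.mark.parametrize("rates,expect", [
        ([0.9, 0.9, 0.9], True),
        ([0.9, 0.8, 0.9, 0.9, 0.9], True),
        ([0.84, 0.84, 0.84], False),
        ([0.85, 0.85, 0.85], True),
        ([0.9, 0.9, 0.8, 0.9, 0.8], False),
    ])
    def test_three_consecutive_days_rule(self, rates, expect):
        assert training_criterion(rates) is expect

    def test_fewer_than_three_days_rejected(self):
        with pytest.raises(InsufficientDataError):
            training_criterion([0.9, 0.9])


# ---------------------------------------------------------------------------
# the two tests against their oracles
# ---------------------------------------------------------------------------

class TestStudentT:
    def test_identical_samples_give_t0_p1(self):
        r = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_closed_form_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        r = unpaired_t_test(a, b)
        t, p = pooled_t_oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_random_samples_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 9))
            r = unpaired_t_test(a, b)
            t, p = pooled_t_oracle(a, b)
            assert r.statistic == pytest.approx(t, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_swap_negates_t_keeps_p(self):
        a, b = [1.0, 3.0, 2.5], [2.0, 4.0, 4.5]
        r1, r2 = unpaired_t_test(a, b), unpaired_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_unequal_means_flagged(self):
        r = unpaired_t_test([1.0, 1.0], [2.0, 2.0])
        assert r.degenerate and r.p_value == 0.0


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert mw_exact_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_permuted_identical_samples_p1(self):
        r = mann_whitney_u([3.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=5), rng.normal(size=6)
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.statistic == r2.statistic
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_exact_p_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(11)
        for n_a in range(1, 7):
            for n_b in range(n_a, 7):
                a = rng.normal(size=n_a)
                b = rng.normal(loc=0.8, size=n_b)
                r = mann_whitney_u(a, b)
                assert r.p_value == pytest.approx(mw_exact_oracle(a, b),
                                                  abs=1e-12)

    def test_tied_data_uses_corrected_normal_approximation(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        b = [2.0, 3.0, 3.0, 5.0, 6.0, 7.0]
        r = mann_whitney_u(a, b)
        assert 0.0 < r.p_value <= 1.0


class TestStars:
    def test_convention_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"


# ---------------------------------------------------------------------------
# per-mouse summaries and group comparisons
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def chemo():
    cfg = TaskConfig(n_success_target=25)
    return run_experiment("chemogenetic", 77, config=cfg,
                          synth_traces=False)


class TestSummaries:
    def test_one_point_per_mouse(self, chemo):
        table = mouse_summary_table(chemo)
        counts = table.groupby(["group", "endpoint"])["mouse"].count()
        assert set(counts) == {6}

    def test_averaging_uses_cno_on_days_only(self, chemo):
        table = mouse_summary_table(chemo, endpoints=("go_success",))
        one = next(iter(chemo.groups["hM3D"].values()))
        included = [l for l in one if l.tags["cno_on"]]
        assert len(included) == 3
        manual = np.mean([session_endpoint(l, "go_success")
                          for l in included])
        got = table[(table["group"] == "hM3D")
                    & (table["mouse"] == included[0].mouse_id)]["value"]
        assert got.iloc[0] == pytest.approx(manual)

    def test_hm3d_detected_against_control(self, chemo):
        comps = summarize_and_compare(chemo, "go_success")
        assert comps["hM3D"].p_value < 0.05
        assert comps["hM3D"].mean_a < comps["hM3D"].mean_b
        assert comps["hM3D"].stars in ("*", "**", "***")

    def test_insufficient_group_size_rejected(self, profiles, control):
        from volstop.engine import ExperimentResult
        cfg = TaskConfig(n_success_target=5)
        logs = {f"m{i}": [run_session(AgentParams(), profiles, cfg, control,
                                      seed=i, synth_traces=False)]
                for i in range(2)}
        tiny = ExperimentResult(
            "chemogenetic",
            {"control": {"m0": logs["m0"]}, "hM3D": {"m1": logs["m1"]}},
            seed=0)
        with pytest.raises(InsufficientDataError):
            summarize_and_compare(tiny, "go_success")

    def test_opto_groups_are_six_and_seven(self):
        cfg = TaskConfig(n_success_target=10)
        expt = run_experiment("optogenetic_feedback", 5, config=cfg,
                              synth_traces=False)
        table = mouse_summary_table(expt, endpoints=("go_success",))
        sizes = table.groupby("group")["mouse"].count().to_dict()
        assert sizes == {"control": 6, "eNpHR": 7}
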