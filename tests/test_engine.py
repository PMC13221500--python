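"""Task-engine tests: detection, trials, scheduler, sessions, experiments."""

import numpy as np
import pytest

from volstop.engine import (ConfigError, ScriptedAgent, TaskConfig,
                            ThresholdRule, detect_threshold_crossing,
                            resolve_threshold, run_experiment, run_go_trial,
                            run_nogo_trial, run_session, schedule_trials)
from volstop.photometry import Trace
from volstop.synth import AgentParams, manipulation_mode


def _trace(values, rate=100.0):
    v = np.asarray(values, dtype=float)
    return Trace(np.arange(v.size) / rate, v, rate)


class TestDetectThresholdCrossing:
    def test_never_reaches_threshold(self):
        sig = _trace(np.zeros(100))
        assert detect_threshold_crossing(sig, 0.5, (0.0, 0.9)) is None

    def test_constant_at_threshold_fires_at_window_start(self):
        sig = _trace(np.full(100, 0.5))
        assert detect_threshold_crossing(sig, 0.5, (0.2, 0.9)) == 0.2

    def test_ramp_matches_linear_scan_oracle(self):
        # 0 -> 1 ramp over 10 s at 100 Hz, threshold 0.5
        v = np.linspace(0.0, 1.0, 1001)
        sig = _trace(v)
        got = detect_threshold_crossing(sig, 0.5, (0.0, 10.0))
        oracle = next(t for t, x in zip(sig.times, v) if x >= 0.5)
        assert got == oracle

    def test_empty_window_rejected(self):
        sig = _trace(np.zeros(100))
        with pytest.raises(ConfigError):
            detect_threshold_crossing(sig, 0.5, (0.9, 0.1))


class TestGoTrial:
    def test_scripted_crossing_event_times(self, quiet_profiles, task,
                                           control):
        res, _, _ = run_go_trial(ScriptedAgent(5.0), quiet_profiles, task,
                                 control, seed=1)
        assert res.outcome == "success"
        ev = dict(res.events)
        assert ev["go_cue"] == 0.0
        assert ev["crossing"] == 5.0
        assert ev["feedback"] == 5.0
        assert ev["reward"] == 6.0
        assert res.response_time == 5.0

    def test_never_crossing_fails_at_window_end(self, quiet_profiles, task,
                                                control):
        res, _, _ = run_go_trial(ScriptedAgent(None), quiet_profiles, task,
                                 control, seed=2)
        assert res.outcome == "failure"
        ev = dict(res.events)
        assert "feedback" not in ev and "reward" not in ev
        assert ev["trial_end"] == task.go_window
        assert res.response_time is None

    def test_withdraw_reward_keeps_crossing_and_feedback(
            self, quiet_profiles, task, control):
        res, traces, gt = run_go_trial(
            ScriptedAgent(5.0), quiet_profiles, task, control,
            variant="GO_no_reward", seed=3)
        ev = dict(res.events)
        assert res.outcome == "success"
        assert ev["crossing"] == 5.0 and ev["feedback"] == 5.0
        assert "reward" not in ev
        # the reward transient is absent from the generated trace
        assert np.all(gt["components"]["M1"]["reward"] == 0.0)

    def test_withdraw_cue_omits_cue_event_and_transient(
            self, quiet_profiles, task, control):
        res, _, gt = run_go_trial(ScriptedAgent(5.0), quiet_profiles, task,
                                  control, variant="GO_no_cue", seed=4)
        assert "go_cue" not in dict(res.events)
        assert np.all(gt["components"]["M1"]["go_cue"] == 0.0)


class TestNogoTrial:
    def test_full_inhibition_feedback_and_reward_times(
            self, quiet_profiles, task, control):
        res, _, _ = run_nogo_trial(ScriptedAgent(None), quiet_profiles, task,
                                   control, seed=5)
        ev = dict(res.events)
        assert res.outcome == "success"
        assert ev["stop_cue"] == task.stop_delay
        assert ev["feedback"] == task.stop_delay + task.hold_duration == 15.0
        assert ev["reward"] == 16.0
        assert res.response_time is None

    def test_post_stop_crossing_fails_with_response_time(
            self, quiet_profiles, task, control):
        res, _, _ = run_nogo_trial(ScriptedAgent(7.0), quiet_profiles, task,
                                   control, seed=6)
        ev = dict(res.events)
        assert res.outcome == "failure"
        assert res.response_time == 7.0
        assert not res.premature
        assert "feedback" not in ev and "reward" not in ev

    def test_premature_crossing_flagged(self, quiet_profiles, task, control):
        res, _, _ = run_nogo_trial(ScriptedAgent(1.0), quiet_profiles, task,
                                   control, seed=7)
        assert res.outcome == "failure"
        assert res.premature
        # the ramp overlaps the cue-evoked transient this early in the
        # trial, so the detector fires slightly before the scripted time
        assert res.response_time == pytest.approx(1.0, abs=0.15)
        assert res.response_time < task.stop_delay
        assert "stop_cue" not in dict(res.events)


class TestScheduler:
    def test_all_go_when_p_go_is_one(self):
        cfg = TaskConfig(p_go=1.0)
        gen = schedule_trials(cfg, 0)
        assert all(next(gen) == "GO" for _ in range(200))

    def test_all_nogo_when_p_go_is_zero(self):
        cfg = TaskConfig(p_go=0.0)
        gen = schedule_trials(cfg, 0)
        assert all(next(gen) == "NOGO" for _ in range(200))

    def test_composition_converges(self, task):
        gen = schedule_trials(task, 123)
        n = 100_000
        frac = sum(next(gen) == "GO" for _ in range(n)) / n
        se = np.sqrt(task.p_go * (1 - task.p_go) / n)
        assert abs(frac - task.p_go) < 3 * se

    def test_deck_scheduler_exact_blocks(self):
        cfg = TaskConfig(scheduler="deck")
        gen = schedule_trials(cfg, 0)
        block = [next(gen) for _ in range(100)]
        assert block.count("GO") == 67


class TestSession:
    def test_perfect_agent_presents_exactly_target(self, profiles, control):
        cfg = TaskConfig(n_success_target=20)
        agent = AgentParams(p_go_success=1.0, p_inhibit=1.0,
                            premature_rate=0.0)
        log = run_session(agent, profiles, cfg, control, seed=1,
                          synth_traces=False)
        assert len(log.trials) == 20
        assert log.successes() == 20

    def test_success_counts_sum_to_target(self, behavior_session):
        log = behavior_session
        assert (log.successes("GO") + log.successes("NOGO")
                == log.config.n_success_target)

    def test_half_success_agent_presents_about_double(self, profiles,
                                                      control):
        cfg = TaskConfig(n_success_target=30, p_go=1.0)
        agent = AgentParams(p_go_success=0.5)
        pres = succ = 0
        for s in range(20):
            log = run_session(agent, profiles, cfg, control, seed=s,
                              synth_traces=False)
            pres += log.presented("GO")
            succ += log.successes("GO")
        assert pres / succ == pytest.approx(2.0, abs=0.15)

    def test_success_rate_identity_recomputable(self, behavior_session):
        log = behavior_session
        for kind in ("GO", "NOGO"):
            raw = [t for t in log.trials if t.trial_type == kind]
            rate = sum(t.outcome == "success" for t in raw) / len(raw)
            assert rate == log.successes(kind) / log.presented(kind)

    def test_event_order_and_reward_delay_invariants(self, behavior_session):
        cfg = behavior_session.config
        order = ("go_cue", "stop_cue", "crossing", "feedback", "reward")
        for tr in behavior_session.trials:
            ev = dict(tr.events)
            present = [ev[c] for c in order if c in ev]
            assert all(a <= b for a, b in zip(present, present[1:]))
            times = [t for _, t in tr.events]
            assert all(a <= b for a, b in zip(times, times[1:]))
            if "reward" in ev:
                assert (ev["reward"] - ev["feedback"]
                        == pytest.approx(cfg.reward_delay, abs=1e-9))

    def test_closed_loop_consistency(self, traced_session):
        # feedback exists iff the detector fired (GO) or the hold completed
        # (NO-GO), iff the generator carries the corresponding transient
        for tr, gt in zip(traced_session.trials, traced_session.ground_truth):
            ev = dict(tr.events)
            if tr.trial_type == "GO":
                assert ("feedback" in ev) == (gt["crossing"] is not None)
            else:
                assert ("feedback" in ev) == (gt["crossing"] is None)
            has_fb_transient = gt["components"]["M1"]["feedback"].any()
            assert has_fb_transient == ("feedback" in ev)

    def test_seed_reproducibility(self, agent, profiles, control):
        cfg = TaskConfig(n_success_target=10)
        a = run_session(agent, profiles, cfg, control, 99, synth_traces=True)
        b = run_session(agent, profiles, cfg, control, 99, synth_traces=True)
        assert [t.events for t in a.trials] == [t.events for t in b.trials]
        assert np.array_equal(a.licks, b.licks)
        assert np.array_equal(a.traces["M1"].values, b.traces["M1"].values)

    def test_fast_path_matches_traced_path(self, agent, profiles, control):
        cfg = TaskConfig(n_success_target=10)
        full = run_session(agent, profiles, cfg, control, 42,
                           synth_traces=True)
        fast = run_session(agent, profiles, cfg, control, 42,
                           synth_traces=False)
        assert ([(t.trial_type, t.outcome) for t in full.trials]
                == [(t.trial_type, t.outcome) for t in fast.trials])
        for a, b in zip(full.trials, fast.trials):
            if a.response_time is not None:
                # detector jitter from baseline noise is a few samples
                assert b.response_time == pytest.approx(a.response_time,
                                                        abs=0.06)

    def test_baseline_threshold_rule(self, profiles):
        cfg = TaskConfig(threshold_rule=ThresholdRule(kind="baseline_k",
                                                      k=2.0))
        thr = resolve_threshold(profiles["M1"], cfg, seed=0)
        # mean + 2 SD of the baseline-block dF/F at the default noise level
        noise = profiles["M1"].noise_sd / profiles["M1"].baseline_F
        assert 0.5 * noise < thr < 4 * noise


class TestExperiment:
    def test_chemogenetic_design_has_three_cno_days(self, profiles):
        cfg = TaskConfig(n_success_target=5)
        expt = run_experiment("chemogenetic", 0, profiles=profiles,
                              config=cfg, n_mice={g: 2 for g in
                                                  ("control", "hM3D", "hM4D")})
        for mice in expt.groups.values():
            for logs in mice.values():
                assert len(logs) == 6
                assert sum(l.tags["cno_on"] for l in logs) == 3
                for log in logs:
                    if not log.tags["cno_on"]:
                        assert log.mode.mode == "control"

    def test_control_group_always_runs_control_mode(self, profiles):
        cfg = TaskConfig(n_success_target=5)
        expt = run_experiment("optogenetic_cue", 1, profiles=profiles,
                              config=cfg)
        assert {m for m in expt.groups} == {"control", "eNpHR"}
        assert len(expt.groups["eNpHR"]) == 7
        assert len(expt.groups["control"]) == 6
        for logs in expt.groups["control"].values():
            assert all(l.mode.mode == "control" for l in logs)

    def test_withdrawal_design_runs_go_only_variants(self, profiles):
        cfg = TaskConfig(n_success_target=4)
        expt = run_experiment("withdrawal", 2, profiles=profiles, config=cfg,
                              n_mice={v: 2 for v in
                                      ("GO", "GO_no_cue", "GO_no_feedback",
                                       "GO_no_reward")})
        for gname, mice in expt.groups.items():
            for logs in mice.values():
                for log in logs:
                    assert {t.trial_type for t in log.trials} == {gname}

    def test_random_reward_sessions_decoupled(self, profiles):
        cfg = TaskConfig(n_success_target=5)
        expt = run_experiment("random_reward", 3, profiles=profiles,
                              config=cfg, n_mice={"random_reward": 2})
        for logs in next(iter(expt.groups.values())).values():
            for log in logs:
                for tr in log.trials:
                    ev = dict(tr.events)
                    assert ev["go_cue"] == ev["reward"]
                    assert "crossing" not in ev
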