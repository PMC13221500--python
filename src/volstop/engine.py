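"""Closed-loop volitional stop-signal task engine.

Implements the paradigm's state machine over the synthetic generator: GO
trials (drive the M1 ΔF/F signal above threshold within 30 s to earn
auditory feedback and, 1 s later, a sucrose reward), NO-GO trials (a stop
cue 2 s after the GO cue; keep the signal below threshold for 13 s),
withdrawal variants of the GO trial (cue / feedback / reward omitted), the
random-reward test, the stochastic 67/33 trial scheduler, session
termination at 50 successes, and the multi-day chemogenetic/optogenetic
experiment designs.

The closed loop is literal: feedback is emitted iff the threshold detector
fires on the agent-driven, noise-bearing M1 ΔF/F decision signal, and the
outcome events are then fed back into the generator so the corresponding
calcium transients appear in (or vanish from) the rendered traces.  A
behavior-only fast path (``synth_traces=False``) skips trace rendering and
places the crossing deterministically at the same grid time the detector
would find under the default noise level; seed-matched outcomes agree
between the two paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import photometry as phot
from . import synth
from .synth import (AgentParams, ManipulationMode, RegionProfile, REGIONS,
                    apply_manipulation, manipulation_mode)

__all__ = [
    "TaskConfig",
    "ThresholdRule",
    "TrialResult",
    "SessionLog",
    "ExperimentResult",
    "ScriptedAgent",
    "detect_threshold_crossing",
    "schedule_trials",
    "run_go_trial",
    "run_nogo_trial",
    "run_session",
    "run_experiment",
    "crossing_offset",
    "resolve_threshold",
    "DESIGNS",
    "GO_VARIANTS",
]

GO_VARIANTS = ("GO", "GO_no_cue", "GO_no_feedback", "GO_no_reward")

#: canonical within-timestamp ordering of logged event classes
EVENT_ORDER = ("trial_start", "go_cue", "stop_cue", "crossing", "feedback",
               "feedback_off", "reward", "trial_end")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdRule:
    """How the feedback threshold is set.

    ``fixed`` uses ``value`` (ΔF/F).  ``baseline_k`` simulates a pre-session
    baseline block and sets threshold = mean + k·SD of its ΔF/F.
    """

    kind: str = "fixed"
    value: float = 0.06
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "baseline_k"):
            raise ConfigError(f"unknown threshold rule {self.kind!r}")


@dataclass(frozen=True)
class TaskConfig:
    """All paradigm constants.

    Tone frequencies are labels only (no audio is synthesized); timing
    defaults follow the published paradigm: 0.5-s feedback tone, 30-s GO
    response window, stop cue 2 s after the GO cue, 13-s hold, 1-s
    feedback-to-reward delay, 10-s inter-trial interval, 67% GO trials, and
    sessions that run to 50 successful trials.
    """

    go_cue_hz: float = 5000.0
    stop_cue_hz: float = 27000.0
    feedback_hz: float = 10000.0
    feedback_duration: float = 0.5
    go_window: float = 30.0
    stop_delay: float = 2.0
    hold_duration: float = 13.0
    reward_delay: float = 1.0
    iti: float = 10.0
    p_go: float = 0.67
    n_success_target: int = 50
    max_trials: int = 500
    threshold_rule: ThresholdRule = field(default_factory=ThresholdRule)
    rate: float = 100.0
    decision_smooth_s: float = 0.5
    scheduler: str = "bernoulli"  # or "deck"
    baseline_duration: float = 20.0

    def __post_init__(self) -> None:
        for name in ("feedback_duration", "go_window", "stop_delay",
                     "hold_duration", "reward_delay", "iti", "rate",
                     "decision_smooth_s", "baseline_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.p_go <= 1.0:
            raise ConfigError("p_go must be in [0, 1]")
        if self.n_success_target < 1:
            raise ConfigError("n_success_target must be >= 1")
        if len({self.go_cue_hz, self.stop_cue_hz, self.feedback_hz}) != 3:
            raise ConfigError("cue frequencies must be pairwise distinct")
        if self.scheduler not in ("bernoulli", "deck"):
            raise ConfigError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class TrialResult:
    """One trial's timestamped record (times relative to trial onset)."""

    trial_index: int
    trial_type: str
    outcome: str  # "success" | "failure"
    events: list[tuple[str, float]]
    response_time: float | None
    threshold_used: float
    duration: float
    premature: bool = False

    def event_time(self, cls: str) -> float | None:
        for c, t in self.events:
            if c == cls:
                return t
        return None


@dataclass
class SessionLog:
    """A full session: config snapshot, trials, licks, traces, ground truth."""

    config: TaskConfig
    mouse_id: str
    day: int
    mode: ManipulationMode
    trials: list[TrialResult]
    trial_onsets: list[float]
    licks: np.ndarray
    threshold: float
    seed_entropy: int | None
    traces: dict[str, phot.Trace] | None = None
    ground_truth: list[dict] = field(default_factory=list)
    tags: dict = field(default_factory=dict)
    max_trials_reached: bool = False
    schema_version: str = "1"

    # -- bookkeeping helpers -------------------------------------------------
    def presented(self, trial_type: str | None = None) -> int:
        return sum(1 for t in self.trials
                   if trial_type is None or t.trial_type == trial_type)

    def successes(self, trial_type: str | None = None) -> int:
        return sum(1 for t in self.trials
                   if (trial_type is None or t.trial_type == trial_type)
                   and t.outcome == "success")

    def reward_times(self) -> np.ndarray:
        out = []
        for onset, tr in zip(self.trial_onsets, self.trials):
            t = tr.event_time("reward")
            if t is not None:
                out.append(onset + t)
        return np.asarray(out)

    @property
    def duration(self) -> float:
        if not self.trials:
            return self.config.baseline_duration
        return self.trial_onsets[-1] + self.trials[-1].duration


@dataclass
class ExperimentResult:
    design: str
    groups: dict[str, dict[str, list[SessionLog]]]
    seed: int | None


class ScriptedAgent:
    """Deterministic agent for worked examples: crosses at ``cross_time``.

    ``cross_time=None`` never crosses.  For NO-GO trials the same time is
    used (a crossing fails the trial); ``None`` fully inhibits.  Lick
    parameters fall back to :class:`AgentParams` defaults.
    """

    def __init__(self, cross_time: float | None,
                 params: AgentParams | None = None):
        self.cross_time = cross_time
        self.params = params or AgentParams()


# ---------------------------------------------------------------------------
# threshold detection and the decision signal
# ---------------------------------------------------------------------------

def detect_threshold_crossing(signal: phot.Trace, threshold: float,
                              window: tuple[float, float]) -> float | None:
    """First time within ``window`` at which ``signal >= threshold``.

    Returns the time of the first sample in the window whose value is at or
    above threshold with the previous sample below it (or the window's first
    sample if it is already at/above threshold); ``None`` if the threshold
    is never reached.  An empty window raises :class:`ConfigError`.
    """
    t0, t1 = window
    if t1 < t0:
        raise ConfigError("empty detection window")
    if t0 < signal.times[0] - 1e-9 or t1 > signal.times[-1] + 1e-9:
        raise ConfigError("detection window outside signal support")
    mask = signal.window(t0, t1)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ConfigError("empty detection window")
    vals = signal.values
    above = vals[idx] >= threshold
    if not above.any():
        return None
    first_in_win = idx[0]
    hits = idx[above]
    for i in hits:
        if i == first_in_win or vals[i - 1] < threshold:
            return float(signal.times[i])
    return None


def _decision_signal(dff: phot.Trace, smooth_s: float) -> phot.Trace:
    """Trailing (causal) moving average of the ΔF/F signal."""
    w = max(int(round(smooth_s * dff.rate)), 1)
    csum = np.concatenate([[0.0], np.cumsum(dff.values)])
    n = dff.values.size
    hi = np.arange(1, n + 1)
    lo = np.maximum(hi - w, 0)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return phot.Trace(dff.times, out, rate=dff.rate,
                      region_name=dff.region_name)


_OFFSET_CACHE: dict[tuple, float] = {}


def crossing_offset(profile_m1: RegionProfile, config: TaskConfig,
                    threshold: float) -> float:
    """Grid time from volitional-ramp onset to detector firing (noiseless).

    Simulates a noiseless GO trial with the ramp at a known time and runs
    the full detection chain (ΔF/F, causal smoothing, threshold scan).
    Used to place scripted crossings and by the behavior-only fast path.
    Raises :class:`ConfigError` if the threshold is unreachable or if the
    cue-evoked response alone trips the detector.
    """
    kern = profile_m1.kernels["volitional_ramp"]
    cue = profile_m1.kernels["go_cue"]
    key = (round(threshold, 12), config.rate, config.decision_smooth_s,
           profile_m1.baseline_F, kern.amplitude, kern.rise_tau,
           kern.decay_tau, cue.amplitude, cue.rise_tau, cue.decay_tau)
    if key in _OFFSET_CACHE:
        return _OFFSET_CACHE[key]
    quiet = replace(profile_m1, noise_sd=0.0)
    t0 = 5.0
    dur = t0 + 8.0
    tt = synth.synthesize_trial_trace(
        quiet, [("go_cue", 0.0), ("volitional_ramp", t0)],
        manipulation_mode("control"), dur, config.rate, seed=0)
    trace = phot.Trace(tt.times, tt.values, config.rate, "M1")
    dff = phot.compute_dff(trace, cue_time=0.0)
    dec = _decision_signal(dff, config.decision_smooth_s)
    c = detect_threshold_crossing(dec, threshold, (0.0, dur - 2.0 / config.rate))
    if c is None:
        raise ConfigError("volitional ramp cannot reach the threshold")
    if c < t0:
        raise ConfigError("cue-evoked response alone crosses the threshold")
    _OFFSET_CACHE[key] = c - t0
    return c - t0


def resolve_threshold(profile_m1: RegionProfile, config: TaskConfig,
                      seed) -> float:
    """Threshold per the configured rule (fixed, or baseline mean + k·SD)."""
    rule = config.threshold_rule
    if rule.kind == "fixed":
        return rule.value
    tt = synth.synthesize_trial_trace(
        profile_m1, [], manipulation_mode("control"),
        config.baseline_duration, config.rate, seed=seed)
    trace = phot.Trace(tt.times, tt.values, config.rate, "M1")
    dff = phot.compute_dff(trace, cue_time=0.0)
    return float(dff.values.mean() + rule.k * dff.values.std(ddof=0))


# ---------------------------------------------------------------------------
# trial scheduling
# ---------------------------------------------------------------------------

def schedule_trials(config: TaskConfig, seed):
    """Lazy stream of trial types ("GO" / "NOGO").

    The default scheduler draws i.i.d. Bernoulli(p_go) per presented trial;
    the "deck" scheduler shuffles fixed-composition blocks of 100.
    """
    rng = synth._rng(seed)
    if config.scheduler == "bernoulli":
        while True:
            yield "GO" if rng.random() < config.p_go else "NOGO"
    else:
        n_go = int(round(config.p_go * 100))
        deck = np.array(["GO"] * n_go + ["NOGO"] * (100 - n_go))
        while True:
            rng.shuffle(deck)
            yield from deck.tolist()


# ---------------------------------------------------------------------------
# single trials
# ---------------------------------------------------------------------------

def _grid(t: float, rate: float) -> float:
    return round(t * rate) / rate


def _plan_go(agent, config: TaskConfig, delta: float, rng) -> float | None:
    """Volitional ramp onset for a GO trial, or None (no attempt)."""
    if isinstance(agent, ScriptedAgent):
        if agent.cross_time is None:
            return None
        return _grid(agent.cross_time - delta, config.rate)
    if rng.random() >= agent.p_go_success:
        return None
    lat = rng.normal(agent.go_latency_mean, agent.go_latency_sd)
    lo = 1.0
    hi = config.go_window - agent.ramp_duration - 1.0
    return _grid(float(np.clip(lat, lo, hi)), config.rate)


def _plan_nogo(agent, config: TaskConfig, delta: float, rng):
    """(ramp onset or None, premature flag) for a NO-GO trial."""
    if isinstance(agent, ScriptedAgent):
        if agent.cross_time is None:
            return None, False
        return (_grid(agent.cross_time - delta, config.rate),
                agent.cross_time < config.stop_delay)
    hold_end = config.stop_delay + config.hold_duration
    if rng.random() < agent.premature_rate:
        target = rng.uniform(delta + 0.05, config.stop_delay - 0.05)
        return _grid(target - delta, config.rate), True
    if rng.random() >= agent.p_inhibit:
        target = rng.uniform(config.stop_delay + 0.3, hold_end - 1.5)
        return _grid(target - delta, config.rate), False
    return None, False


def _detect_on_trace(profile_m1, events, mode, det_dur, config, threshold,
                     noise) -> float | None:
    tt = synth.synthesize_trial_trace(
        profile_m1, events, mode, det_dur, config.rate, seed=None, noise=noise)
    trace = phot.Trace(tt.times, tt.values, config.rate, "M1")
    dff = phot.compute_dff(trace, cue_time=0.0)
    dec = _decision_signal(dff, config.decision_smooth_s)
    win_end = det_dur - 2.0 / config.rate
    return detect_threshold_crossing(dec, threshold, (0.0, win_end))


def _order_events(events: list[tuple[str, float]]) -> list[tuple[str, float]]:
    return sorted(events, key=lambda e: (e[1], EVENT_ORDER.index(e[0])))


def _synth_regions(profiles, regions, synth_events, mode, duration, config,
                   region_seeds, m1_noise):
    traces, comps = {}, {}
    for rname in regions:
        noise = m1_noise if rname == "M1" else None
        tt = synth.synthesize_trial_trace(
            profiles[rname], synth_events, mode, duration, config.rate,
            seed=region_seeds[rname], noise=noise)
        traces[rname] = phot.Trace(tt.times, tt.values, config.rate, rname)
        comps[rname] = tt.components
    return traces, comps


def _trial_streams(seed, need_regions: bool = True):
    """Per-trial substreams: behavior draws and per-region noise.

    The spawn layout is identical whether or not region streams are
    materialised, so the behavior-only path draws the same numbers as the
    traced path under matched seeds.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + len(REGIONS))
    rng = np.random.default_rng(children[0])
    if not need_regions:
        return rng, None
    region_seeds = {r: np.random.default_rng(children[1 + i])
                    for i, r in enumerate(REGIONS)}
    return rng, region_seeds


def run_go_trial(agent, profiles, config: TaskConfig, mode: ManipulationMode,
                 variant: str = "GO", seed=0, threshold: float | None = None,
                 synth_traces: bool = True, regions=REGIONS,
                 _delta: float | None = None):
    """Run one GO trial (or a withdrawal variant of it).

    Returns ``(TrialResult, traces, ground_truth)``; ``traces`` is None on
    the behavior-only path.  Omitted events in withdrawal variants are also
    omitted from the generator, so their transients vanish from the traces.
    """
    if variant not in GO_VARIANTS:
        raise ConfigError(f"unknown GO variant {variant!r}")
    rng, region_seeds = _trial_streams(seed, need_regions=synth_traces)
    if threshold is None:
        threshold = resolve_threshold(profiles["M1"], config, seed=0)
    if _delta is None:
        _delta = crossing_offset(profiles["M1"], config, threshold)
    ramp_start = _plan_go(agent, config, _delta, rng)

    has_cue = variant != "GO_no_cue"
    cue_events = [("go_cue", 0.0)] if has_cue else []
    ramp_events = ([("volitional_ramp", ramp_start)]
                   if ramp_start is not None else [])

    max_dur = config.go_window + config.reward_delay + config.iti + 1.0
    if synth_traces:
        m1_noise = region_seeds["M1"].normal(
            0.0, profiles["M1"].noise_sd, size=int(round(max_dur * config.rate)))
        det_dur = config.go_window + 2.0 / config.rate
        crossing = _detect_on_trace(
            profiles["M1"], cue_events + ramp_events, mode, det_dur, config,
            threshold, m1_noise)
        if crossing is not None and crossing > config.go_window:
            crossing = None
    else:
        m1_noise = None
        crossing = (None if ramp_start is None
                    else _grid(ramp_start + _delta, config.rate))
        if crossing is not None and crossing > config.go_window:
            crossing = None

    events: list[tuple[str, float]] = list(cue_events)
    synth_events: list[tuple[str, float]] = list(cue_events) + ramp_events
    if crossing is not None:
        outcome = "success"
        events.append(("crossing", crossing))
        if variant != "GO_no_feedback":
            events.append(("feedback", crossing))
            events.append(("feedback_off", crossing + config.feedback_duration))
            synth_events.append(("feedback", crossing))
        reward_t = crossing + config.reward_delay
        if variant != "GO_no_reward":
            events.append(("reward", reward_t))
            synth_events.append(("reward", reward_t))
        end = reward_t
        response_time = crossing
    else:
        outcome = "failure"
        end = config.go_window
        reward_t = None
        response_time = None
    events.append(("trial_end", end))
    duration = end + config.iti

    traces = comps = None
    if synth_traces:
        traces, comps = _synth_regions(
            profiles, regions, synth_events, mode, duration, config,
            region_seeds, m1_noise)

    gt = {
        "variant": variant, "attempt": ramp_start is not None,
        "ramp_start": ramp_start, "crossing": crossing,
        "anchors": {
            "go_cue": 0.0,
            "stop_cue": None,
            "volitional": crossing,
            "feedback": crossing,
            "reward": (crossing + config.reward_delay
                       if crossing is not None else None),
        },
        "components": comps,
    }
    result = TrialResult(
        trial_index=-1, trial_type=variant, outcome=outcome,
        events=_order_events(events), response_time=response_time,
        threshold_used=threshold, duration=duration)
    return result, traces, gt


def run_nogo_trial(agent, profiles, config: TaskConfig,
                   mode: ManipulationMode, seed=0,
                   threshold: float | None = None, synth_traces: bool = True,
                   regions=REGIONS, _delta: float | None = None):
    """Run one NO-GO trial.

    The stop cue sounds ``stop_delay`` after the GO cue; holding the signal
    below threshold through the hold period earns feedback at hold end and
    reward ``reward_delay`` later.  Any crossing within the monitored window
    is a failure (crossings before the stop cue are flagged premature and
    the stop cue is not played); failures abort the trial at the crossing.
    """
    rng, region_seeds = _trial_streams(seed, need_regions=synth_traces)
    if threshold is None:
        threshold = resolve_threshold(profiles["M1"], config, seed=0)
    if _delta is None:
        _delta = crossing_offset(profiles["M1"], config, threshold)
    ramp_start, premature_plan = _plan_nogo(agent, config, _delta, rng)

    hold_end = config.stop_delay + config.hold_duration
    cue_events = [("go_cue", 0.0)]
    ramp_events = ([("volitional_ramp", ramp_start)]
                   if ramp_start is not None else [])
    max_dur = hold_end + config.reward_delay + config.iti + 1.0
    if synth_traces:
        m1_noise = region_seeds["M1"].normal(
            0.0, profiles["M1"].noise_sd, size=int(round(max_dur * config.rate)))
        det_dur = hold_end + 2.0 / config.rate
        # stop cue has no M1 kernel by default but is part of the stimulus
        # stream; include it for detection (it precedes any post-stop crossing)
        crossing = _detect_on_trace(
            profiles["M1"], cue_events + [("stop_cue", config.stop_delay)]
            + ramp_events, mode, det_dur, config, threshold, m1_noise)
        if crossing is not None and crossing > hold_end:
            crossing = None
    else:
        m1_noise = None
        crossing = (None if ramp_start is None
                    else _grid(ramp_start + _delta, config.rate))
        if crossing is not None and crossing > hold_end:
            crossing = None

    premature = crossing is not None and crossing < config.stop_delay
    stop_played = crossing is None or not premature

    events: list[tuple[str, float]] = list(cue_events)
    synth_events: list[tuple[str, float]] = list(cue_events) + ramp_events
    if stop_played:
        events.append(("stop_cue", config.stop_delay))
        synth_events.append(("stop_cue", config.stop_delay))
    if crossing is None:
        outcome = "success"
        fb = hold_end
        reward_t = fb + config.reward_delay
        events += [("feedback", fb),
                   ("feedback_off", fb + config.feedback_duration),
                   ("reward", reward_t)]
        synth_events += [("feedback", fb), ("reward", reward_t)]
        end = reward_t
        response_time = None
    else:
        outcome = "failure"
        events.append(("crossing", crossing))
        end = crossing
        reward_t = None
        response_time = crossing
    events.append(("trial_end", end))
    duration = end + config.iti

    traces = comps = None
    if synth_traces:
        traces, comps = _synth_regions(
            profiles, regions, synth_events, mode, duration, config,
            region_seeds, m1_noise)

    gt = {
        "variant": "NOGO", "attempt": ramp_start is not None,
        "ramp_start": ramp_start, "crossing": crossing,
        "anchors": {
            "go_cue": 0.0,
            "stop_cue": config.stop_delay if stop_played else None,
            "volitional": crossing,
            "feedback": hold_end if crossing is None else None,
            "reward": reward_t,
        },
        "components": comps,
    }
    result = TrialResult(
        trial_index=-1, trial_type="NOGO", outcome=outcome,
        events=_order_events(events), response_time=response_time,
        threshold_used=threshold, duration=duration, premature=premature)
    return result, traces, gt


def _run_random_reward_trial(agent, profiles, config, mode, seed,
                             threshold, synth_traces, regions):
    """Random-reward test trial: GO cue and reward co-played, decoupled
    from the signal."""
    _, region_seeds = _trial_streams(seed, need_regions=synth_traces)
    events = [("go_cue", 0.0), ("reward", 0.0)]
    end = config.reward_delay
    duration = end + config.iti
    traces = comps = None
    if synth_traces:
        traces, comps = _synth_regions(
            profiles, regions, events, mode, duration, config,
            region_seeds, None)
    gt = {"variant": "random_reward", "attempt": False, "ramp_start": None,
          "crossing": None,
          "anchors": {"go_cue": 0.0, "stop_cue": None, "volitional": None,
                      "feedback": None, "reward": 0.0},
          "components": comps}
    result = TrialResult(
        trial_index=-1, trial_type="random_reward", outcome="success",
        events=_order_events(events + [("trial_end", end)]),
        response_time=None, threshold_used=threshold, duration=duration)
    return result, traces, gt


# ---------------------------------------------------------------------------
# sessions and experiments
# ---------------------------------------------------------------------------

def run_session(agent, profiles, config: TaskConfig, mode: ManipulationMode,
                seed, mouse_id: str = "m0", day: int = 1,
                synth_traces: bool = True, regions=REGIONS,
                go_variant: str = "GO", session_kind: str = "task",
                tags: dict | None = None) -> SessionLog:
    """Run trials until ``n_success_target`` successes (both types counted)
    or ``max_trials``; returns the assembled :class:`SessionLog`.

    ``go_variant`` substitutes a withdrawal variant for every GO trial;
    ``session_kind="random_reward"`` runs the random-reward test instead of
    the closed-loop task.  The manipulation in ``mode`` affects behavior via
    :func:`synth.apply_manipulation` and the traces via the generator's
    gain model.
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
        entropy = None
    else:
        root = np.random.SeedSequence(seed)
        entropy = int(seed) if np.isscalar(seed) else None
    base_ss, lick_ss, sched_ss = root.spawn(3)
    _pool: list[np.random.SeedSequence] = []

    def _next_trial_ss() -> np.random.SeedSequence:
        if not _pool:
            _pool.extend(root.spawn(64))
        return _pool.pop(0)

    eff_agent = agent
    if not isinstance(agent, ScriptedAgent):
        eff_agent, _ = apply_manipulation(agent, profiles, mode)
    threshold = resolve_threshold(profiles["M1"], config,
                                  seed=np.random.default_rng(base_ss))
    delta = crossing_offset(profiles["M1"], config, threshold)

    sched = schedule_trials(config, np.random.default_rng(sched_ss))
    trials: list[TrialResult] = []
    onsets: list[float] = []
    gts: list[dict] = []
    trial_traces: list[dict[str, phot.Trace] | None] = []
    t_cursor = config.baseline_duration
    successes = 0
    idx = 0
    while successes < config.n_success_target and idx < config.max_trials:
        trial_ss = _next_trial_ss()
        if session_kind == "random_reward":
            res, traces, gt = _run_random_reward_trial(
                eff_agent, profiles, config, mode, trial_ss, threshold,
                synth_traces, regions)
        else:
            ttype = next(sched)
            if ttype == "GO":
                res, traces, gt = run_go_trial(
                    eff_agent, profiles, config, mode, variant=go_variant,
                    seed=trial_ss, threshold=threshold,
                    synth_traces=synth_traces, regions=regions, _delta=delta)
            else:
                res, traces, gt = run_nogo_trial(
                    eff_agent, profiles, config, mode, seed=trial_ss,
                    threshold=threshold, synth_traces=synth_traces,
                    regions=regions, _delta=delta)
        res.trial_index = idx
        trials.append(res)
        onsets.append(t_cursor)
        gts.append(gt)
        trial_traces.append(traces)
        t_cursor += res.duration
        if res.outcome == "success":
            successes += 1
        idx += 1

    flagged = successes < config.n_success_target

    session_traces = None
    if synth_traces:
        # baseline block per region, then concatenated trial traces
        session_traces = {}
        base_region_ss = base_ss.spawn(len(regions))
        for i, rname in enumerate(regions):
            tt = synth.synthesize_trial_trace(
                profiles[rname], [], mode, config.baseline_duration,
                config.rate, seed=np.random.default_rng(base_region_ss[i]))
            parts_t = [tt.times]
            parts_v = [tt.values]
            offset = config.baseline_duration
            for traces, res in zip(trial_traces, trials):
                tr = traces[rname]
                parts_t.append(tr.times + offset)
                parts_v.append(tr.values)
                offset += res.duration
            session_traces[rname] = phot.Trace(
                np.concatenate(parts_t), np.concatenate(parts_v),
                config.rate, rname)

    lick_params = (eff_agent.params if isinstance(eff_agent, ScriptedAgent)
                   else eff_agent)
    log = SessionLog(
        config=config, mouse_id=mouse_id, day=day, mode=mode, trials=trials,
        trial_onsets=onsets, licks=np.zeros(0), threshold=threshold,
        seed_entropy=entropy, traces=session_traces, ground_truth=gts,
        tags=dict(tags or {}), max_trials_reached=flagged)
    log.licks = synth.simulate_licks(
        log.reward_times(), lick_params, log.duration,
        np.random.default_rng(lick_ss))
    return log


DESIGNS = ("chemogenetic", "optogenetic_feedback", "optogenetic_cue",
           "optogenetic_reward", "random_reward", "withdrawal")

_OPTO_MODE = {
    "optogenetic_feedback": "eNpHR_at_feedback",
    "optogenetic_cue": "eNpHR_at_cue",
    "optogenetic_reward": "eNpHR_at_reward",
}


def run_experiment(design: str, seed, agent: AgentParams | None = None,
                   profiles: dict[str, RegionProfile] | None = None,
                   config: TaskConfig | None = None,
                   n_mice: dict[str, int] | None = None,
                   days: int | None = None, synth_traces: bool = False,
                   regions=REGIONS) -> ExperimentResult:
    """Run a multi-day, multi-group experiment design.

    ``chemogenetic``: control/hM3D/hM4D × 6 mice, 6 days with CNO on
    alternate days (3 CNO-on days, tagged for averaging; the manipulation is
    active only on CNO days).  ``optogenetic_*``: control (6) vs eNpHR (7),
    3 days, 1-s event-locked suppression on every trial.  ``withdrawal``:
    GO-only sessions per withdrawal variant, 6 mice each.
    ``random_reward``: cue+reward co-delivery test sessions.
    """
    if design not in DESIGNS:
        raise ConfigError(f"unknown design {design!r}")
    agent = agent or AgentParams()
    profiles = profiles or synth.default_profiles()
    config = config or TaskConfig()

    if design == "chemogenetic":
        group_modes = {"control": "control", "hM3D": "hM3D", "hM4D": "hM4D"}
        default_n = {g: 6 for g in group_modes}
        days = days or 6
    elif design in _OPTO_MODE:
        group_modes = {"control": "control", "eNpHR": _OPTO_MODE[design]}
        default_n = {"control": 6, "eNpHR": 7}
        days = days or 3
    elif design == "withdrawal":
        group_modes = {v: "control" for v in GO_VARIANTS}
        default_n = {v: 6 for v in GO_VARIANTS}
        days = days or 1
        config = replace(config, p_go=1.0)
    else:  # random_reward
        group_modes = {"random_reward": "control"}
        default_n = {"random_reward": 6}
        days = days or 1

    n_mice = {**default_n, **(n_mice or {})}
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    n_sessions = sum(n_mice[g] for g in group_modes) * days
    children = iter(root.spawn(n_sessions))

    groups: dict[str, dict[str, list[SessionLog]]] = {}
    for gname, mode_name in group_modes.items():
        groups[gname] = {}
        for m in range(n_mice[gname]):
            mouse_id = f"{gname}_{m}"
            logs = []
            for day in range(1, days + 1):
                ss = next(children)
                tags = {}
                mode = manipulation_mode(mode_name)
                if design == "chemogenetic":
                    cno_on = day % 2 == 0
                    tags["cno_on"] = cno_on
                    tags["include"] = cno_on
                    if not cno_on:
                        mode = manipulation_mode("control")
                else:
                    tags["include"] = True
                kind = "random_reward" if design == "random_reward" else "task"
                variant = gname if design == "withdrawal" else "GO"
                logs.append(run_session(
                    agent, profiles, config, mode, ss, mouse_id=mouse_id,
                    day=day, synth_traces=synth_traces, regions=regions,
                    go_variant=variant, session_kind=kind, tags=tags))
            groups[gname][mouse_id] = logs
    seed_int = int(seed) if np.isscalar(seed) else None
    return ExperimentResult(design=design, groups=groups, seed=seed_int)
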