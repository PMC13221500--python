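"""Synthetic calcium-trace and behavior generator.

Emulates the statistical structure of multi-region fiber-photometry
recordings during a closed-loop volitional stop-signal task: each brain
region (M1 under GCaMP6f, GPe/STN under jRGECO1a) produces a
baseline-plus-Gaussian-noise fluorescence signal with additive, stereotyped
transients time-locked to task events (GO cue, stop cue, auditory feedback,
reward, and the volitional threshold approach).  A parametric agent model
supplies trial-by-trial behavior (whether the animal drives or withholds the
controlled signal, response latencies, reward licking), and manipulation
modes encode chemogenetic/optogenetic perturbations as multiplicative
effects on agent parameters and on kernel gains.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EVENT_CLASSES",
    "TransientKernel",
    "RegionProfile",
    "AgentParams",
    "ManipulationMode",
    "TrialTrace",
    "evaluate_kernel",
    "synthesize_trial_trace",
    "simulate_licks",
    "apply_manipulation",
    "default_profiles",
    "manipulation_mode",
    "MODE_NAMES",
]

#: Event classes every region profile must provide a kernel for.
EVENT_CLASSES = ("go_cue", "stop_cue", "feedback", "reward", "volitional_ramp")

REGIONS = ("M1", "GPe", "STN")


class ParameterError(ValueError):
    """Invalid generator parameter."""


class SchemaError(KeyError):
    """Unknown event class or malformed event record."""


@dataclass(frozen=True)
class TransientKernel:
    """Difference-of-exponentials calcium transient, peak-normalized.

    The kernel is ``amplitude * (exp(-t/decay_tau) - exp(-t/rise_tau))``
    rescaled so its maximum equals ``amplitude`` (ΔF/F units).  This family
    gives the fast-rise / slow-decay shape of GCaMP-type indicators;
    ``kernel(0) == 0`` and the kernel decays to zero.

    Parameters
    ----------
    amplitude : float
        Peak ΔF/F of the transient.  Zero means "region does not respond".
    rise_tau, decay_tau : float
        Time constants in seconds, ``0 < rise_tau < decay_tau``.
    """

    amplitude: float
    rise_tau: float
    decay_tau: float

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ParameterError("kernel time constants must be positive")
        if not self.rise_tau < self.decay_tau:
            raise ParameterError("rise_tau must be smaller than decay_tau")
        if self.amplitude < 0:
            raise ParameterError("kernel amplitude must be non-negative")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum (closed form)."""
        r, d = self.rise_tau, self.decay_tau
        return (r * d) / (d - r) * math.log(d / r)

    @property
    def _norm(self) -> float:
        t = self.peak_time
        return math.exp(-t / self.decay_tau) - math.exp(-t / self.rise_tau)


def evaluate_kernel(kernel: TransientKernel, t: np.ndarray) -> np.ndarray:
    """Evaluate ``kernel`` on a grid of times (s, relative to event onset).

    Negative times evaluate to zero; the peak value equals
    ``kernel.amplitude`` up to grid resolution.  A zero-length grid returns
    an empty array.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return np.zeros(0)
    if kernel.amplitude == 0.0:
        return np.zeros(t.shape)
    out = np.zeros(t.shape)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (
        kernel.amplitude
        / kernel._norm
        * (np.exp(-tp / kernel.decay_tau) - np.exp(-tp / kernel.rise_tau))
    )
    return out


@dataclass
class RegionProfile:
    """Fluorescence model for one recorded region."""

    region_name: str
    baseline_F: float
    noise_sd: float
    kernels: dict[str, TransientKernel]
    drift_per_s: float = 0.0  # optional linear drift, a.u./s (off by default)

    def __post_init__(self) -> None:
        if self.baseline_F <= 0:
            raise ParameterError("baseline_F must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        missing = set(EVENT_CLASSES) - set(self.kernels)
        if missing:
            raise ParameterError(f"profile missing kernels for {sorted(missing)}")


@dataclass
class AgentParams:
    """Parametric behavioral model of a trained mouse.

    Probabilities are per-trial; latencies/durations in seconds; lick_rate in
    licks/s.  ``premature_rate`` is the probability of a NO-GO crossing
    before the stop cue; ``p_inhibit`` the probability of withholding for the
    full hold period once the stop cue has sounded.
    """

    p_go_success: float = 0.9
    go_latency_mean: float = 4.0
    go_latency_sd: float = 1.5
    ramp_duration: float = 2.0
    p_inhibit: float = 0.75
    premature_rate: float = 0.01
    lick_rate: float = 5.0
    lick_bout_duration: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_go_success", "p_inhibit", "premature_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        for name in ("go_latency_mean", "go_latency_sd", "ramp_duration",
                     "lick_bout_duration"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.lick_rate < 0:
            raise ParameterError("lick_rate must be non-negative")


@dataclass(frozen=True)
class ManipulationMode:
    """A chemogenetic/optogenetic perturbation as multiplicative effects.

    ``behavior_effects`` multiply :class:`AgentParams` fields.  Entries for
    ``p_inhibit`` are applied on the failure rate (``1 - p``) so the result
    stays a probability: a gain g maps ``p -> 1 - (1 - p)/g``; other
    probability fields are multiplied directly and capped at 1.

    ``signal_effects`` map ``(region, event_class)`` to gains on kernel
    amplitudes.  For optogenetic (windowed) modes the gain applies only
    within a 1-s window locked to the affected event; chemogenetic gains
    scale the whole kernel.
    """

    mode: str
    behavior_effects: dict[str, float] = field(default_factory=dict)
    signal_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    windowed: bool = False
    window_s: float = 1.0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.signal_effects.values()):
            raise ParameterError("signal gains must be non-negative")


def _mode_table() -> dict[str, ManipulationMode]:
    return {
        "control": ManipulationMode("control"),
        "hM3D": ManipulationMode(
            "hM3D",
            behavior_effects={"p_go_success": 0.6, "p_inhibit": 2.5,
                              "lick_rate": 0.7},
            signal_effects={("GPe", "feedback"): 0.5},
        ),
        "hM4D": ManipulationMode(
            "hM4D",
            signal_effects={("M1", "reward"): 0.6, ("STN", "feedback"): 0.5,
                            ("GPe", "feedback"): 0.6},
        ),
        "eNpHR_at_feedback": ManipulationMode(
            "eNpHR_at_feedback",
            behavior_effects={"p_go_success": 0.7, "go_latency_mean": 1.3,
                              "p_inhibit": 2.0},
            signal_effects={("STN", "feedback"): 0.5, ("STN", "reward"): 0.5},
            windowed=True,
        ),
        "eNpHR_at_cue": ManipulationMode("eNpHR_at_cue", windowed=True),
        "eNpHR_at_reward": ManipulationMode(
            "eNpHR_at_reward",
            signal_effects={("STN", "volitional_ramp"): 0.6,
                            ("STN", "feedback"): 0.6, ("STN", "reward"): 0.6},
            windowed=True,
        ),
    }


MODE_NAMES = tuple(_mode_table())


def manipulation_mode(name: str) -> ManipulationMode:
    """Look up a preset mode by name (raises ParameterError if unknown)."""
    table = _mode_table()
    if name not in table:
        raise ParameterError(f"unknown manipulation mode {name!r}")
    return table[name]


def default_profiles() -> dict[str, RegionProfile]:
    """Default region profiles.

    Amplitudes/time constants are free parameters of the generator (the
    source figures are unscaled); defaults are chosen for clear temporal
    separation of the arrow-marked components: the volitional ramp is slow
    and small relative to the sharp feedback/reward transients, the stop-cue
    response is absent in M1 and present in GPe/STN, and auditory-cue
    responses sit below the feedback threshold on the decision signal.
    """
    cue = dict(rise_tau=0.05, decay_tau=0.3)
    fb = dict(rise_tau=0.08, decay_tau=0.3)
    rw = dict(rise_tau=0.2, decay_tau=0.6)
    vol = dict(rise_tau=0.4, decay_tau=0.8)

    def prof(name, go, stop, v, f, r):
        return RegionProfile(
            region_name=name, baseline_F=1.0, noise_sd=0.002,
            kernels={
                "go_cue": TransientKernel(go, **cue),
                "stop_cue": TransientKernel(stop, **cue),
                "volitional_ramp": TransientKernel(v, **vol),
                "feedback": TransientKernel(f, **fb),
                "reward": TransientKernel(r, **rw),
            },
        )

    return {
        "M1": prof("M1", 0.05, 0.0, 0.08, 1.0, 1.0),
        "GPe": prof("GPe", 0.5, 0.3, 0.08, 1.0, 0.8),
        "STN": prof("STN", 0.5, 0.3, 0.08, 1.0, 0.9),
    }


@dataclass
class TrialTrace:
    """A synthesized single-region trial trace with its ground truth.

    ``values = baseline + drift + noise + sum(components.values())`` exactly,
    so tests can reconstruct the trace from the returned parts.
    """

    times: np.ndarray
    values: np.ndarray
    rate: float
    region_name: str
    baseline_F: float
    components: dict[str, np.ndarray]
    noise: np.ndarray


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synthesize_trial_trace(
    profile: RegionProfile,
    events: list[tuple[str, float]],
    mode: ManipulationMode,
    duration: float,
    rate: float,
    seed,
    noise: np.ndarray | None = None,
) -> TrialTrace:
    """Render one trial's fluorescence trace for a region.

    ``events`` is a list of ``(event_class, time_s)`` with times in
    ``[0, duration]``.  Each event adds its class kernel scaled by the
    mode's gain for ``(region, class)``; for windowed (optogenetic) modes
    the gain applies only within ``mode.window_s`` seconds of the event.
    ``noise`` lets the caller reuse a pre-drawn noise array (closed-loop
    re-rendering with identical noise); otherwise Gaussian noise is drawn
    from ``seed``.
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if duration < 0:
        raise ParameterError("duration must be non-negative")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    components = {cls: np.zeros(n) for cls in EVENT_CLASSES}
    for cls, ev_t in events:
        if cls not in components:
            raise SchemaError(f"unknown event class {cls!r}")
        if not 0.0 <= ev_t <= duration:
            raise ParameterError(
                f"event {cls!r} at {ev_t} s outside [0, {duration}] s")
        kern = profile.kernels[cls]
        contrib = evaluate_kernel(kern, t - ev_t)
        gain = mode.signal_effects.get((profile.region_name, cls), 1.0)
        if gain != 1.0:
            if mode.windowed:
                inwin = (t >= ev_t) & (t < ev_t + mode.window_s)
                contrib[inwin] *= gain
            else:
                contrib *= gain
        components[cls] += contrib
    if noise is None:
        noise = _rng(seed).normal(0.0, profile.noise_sd, size=n)
    else:
        noise = np.asarray(noise, dtype=float)[:n]
        if noise.size != n:
            raise ParameterError("provided noise array is too short")
    values = profile.baseline_F + profile.drift_per_s * t + noise
    for arr in components.values():
        values = values + arr
    return TrialTrace(
        times=t, values=values, rate=rate, region_name=profile.region_name,
        baseline_F=profile.baseline_F, components=components, noise=noise,
    )


def simulate_licks(
    reward_times,
    params: AgentParams,
    session_duration: float,
    seed,
) -> np.ndarray:
    """Homogeneous-Poisson lick train inside post-reward bouts.

    Licks occur at rate ``params.lick_rate`` within
    ``[reward, reward + lick_bout_duration]`` for each reward and nowhere
    else.  Returns sorted timestamps (s).
    """
    rng = _rng(seed)
    reward_times = np.asarray(list(reward_times), dtype=float)
    if reward_times.size == 0 or params.lick_rate == 0.0:
        return np.zeros(0)
    if np.any(np.diff(reward_times) < 0):
        raise ParameterError("reward_times must be sorted")
    out: list[np.ndarray] = []
    for r in reward_times:
        bout_end = min(r + params.lick_bout_duration, session_duration)
        span = bout_end - r
        if span <= 0:
            continue
        k = rng.poisson(params.lick_rate * span)
        if k:
            out.append(r + rng.uniform(0.0, span, size=k))
    if not out:
        return np.zeros(0)
    return np.sort(np.concatenate(out))


def apply_manipulation(
    agent: AgentParams,
    profiles: dict[str, RegionProfile],
    mode: ManipulationMode,
) -> tuple[AgentParams, dict[str, RegionProfile]]:
    """Return deep-modified copies of the agent and profiles under ``mode``.

    Control returns field-identical copies.  Behavior effects multiply agent
    fields (``p_inhibit`` via failure-rate scaling, probabilities capped at
    1).  Non-windowed signal effects are baked into kernel amplitudes;
    windowed (optogenetic) effects are inherently time-locked and are left
    to :func:`synthesize_trial_trace`, so profiles pass through unchanged
    for those modes.
    """
    if mode.mode not in MODE_NAMES:
        raise ParameterError(f"unknown manipulation mode {mode.mode!r}")
    changes: dict[str, float] = {}
    for name, gain in mode.behavior_effects.items():
        if not hasattr(agent, name):
            raise ParameterError(f"unknown agent field {name!r}")
        value = getattr(agent, name)
        if name == "p_inhibit":
            new = 1.0 - (1.0 - value) / gain
        else:
            new = value * gain
        if name in ("p_go_success", "p_inhibit", "premature_rate"):
            new = min(max(new, 0.0), 1.0)
        changes[name] = new
    new_agent = replace(agent, **changes)
    new_profiles = copy.deepcopy(profiles)
    if not mode.windowed:
        for region, prof in new_profiles.items():
            for cls, kern in prof.kernels.items():
                gain = mode.signal_effects.get((region, cls), 1.0)
                if gain != 1.0:
                    prof.kernels[cls] = replace(
                        kern, amplitude=kern.amplitude * gain)
    return new_agent, new_profiles
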