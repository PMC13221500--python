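"""Fiber-photometry signal processing.

Smoothing, ΔF/F conversion, peri-event alignment and component-peak
extraction.  The processing chain mirrors standard photometry practice for
this task: a 20-ms moving-average filter stepped every 10 ms, ΔF/F against
a cue-locked baseline F0 (the 10 ms following cue onset), reward-aligned
windows (15 s before / 10 s after by default), and per-component peak
search in event-locked windows (the arrow-marked cue / volitional /
feedback / reward / stop components of the source traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "AlignedSegment",
    "ComponentPeaks",
    "moving_average",
    "compute_dff",
    "align_to_event",
    "extract_component_peaks",
    "DEFAULT_PEAK_WINDOWS",
]


class PhotometryError(ValueError):
    pass


class AlignmentError(PhotometryError):
    pass


@dataclass
class Trace:
    """Uniformly sampled single-region time series (raw F or ΔF/F)."""

    times: np.ndarray
    values: np.ndarray
    rate: float
    region_name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise PhotometryError("times and values must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - 1.0 / self.rate) > 1e-9):
                raise PhotometryError(
                    "trace not uniformly sampled at the stated rate")
        if not np.all(np.isfinite(self.values)):
            raise PhotometryError("trace contains non-finite values")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= t <= t1 (1e-9 tolerance)."""
        return (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)


def moving_average(trace: Trace, span_ms: float = 20.0,
                   step_ms: float = 10.0) -> Trace:
    """Centered moving-average filter (span 20 ms, step 10 ms by default).

    Each output sample at time ``t0 + k*step`` is the arithmetic mean of the
    input samples within ``[t - span/2, t + span/2]`` (window truncated, not
    padded, at the edges).  Output rate is ``1000/step_ms`` Hz.
    """
    if step_ms <= 0 or span_ms < step_ms:
        raise PhotometryError("need span_ms >= step_ms > 0")
    span, step = span_ms / 1000.0, step_ms / 1000.0
    if span < 1.0 / trace.rate - 1e-12:
        raise PhotometryError("span shorter than one sample period")
    t0 = trace.times[0] if trace.times.size else 0.0
    t_end = trace.times[-1] if trace.times.size else 0.0
    n_out = int(np.floor((t_end - t0) / step + 1e-9)) + 1 if trace.times.size else 0
    out_t = t0 + np.arange(n_out) * step
    half = span / 2.0
    # index ranges via searchsorted on the uniform grid (half-open -> closed)
    lo = np.searchsorted(trace.times, out_t - half - 1e-9, side="left")
    hi = np.searchsorted(trace.times, out_t + half + 1e-9, side="right")
    csum = np.concatenate([[0.0], np.cumsum(trace.values)])
    out_v = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
    return Trace(out_t, out_v, rate=1000.0 / step_ms,
                 region_name=trace.region_name)


def compute_dff(trace: Trace, cue_time: float,
                baseline_ms: float = 10.0) -> Trace:
    """ΔF/F = (F − F0)/F0 with F0 the mean F within ``baseline_ms`` of cue.

    F0 is the mean of the samples in ``[cue_time, cue_time + baseline_ms]``
    (the baseline window immediately follows cue onset).  Raises if the
    window lies outside the trace or the baseline is non-positive.
    """
    hi = cue_time + baseline_ms / 1000.0
    if cue_time < trace.times[0] - 1e-9 or hi > trace.times[-1] + 1e-9:
        raise PhotometryError("baseline window outside trace support")
    mask = trace.window(cue_time, hi)
    if not mask.any():
        raise PhotometryError("baseline window contains no samples")
    f0 = float(trace.values[mask].mean())
    if f0 <= 0:
        raise PhotometryError("degenerate baseline: F0 must be positive")
    return Trace(trace.times, (trace.values - f0) / f0, rate=trace.rate,
                 region_name=trace.region_name)


@dataclass
class AlignedSegment:
    """A trace segment on a relative time base (0 = alignment event)."""

    rel_times: np.ndarray
    values: np.ndarray
    rate: float
    alignment_class: str
    alignment_time: float
    pre: float
    post: float
    truncated: bool = False
    region_name: str = ""


def align_to_event(trace: Trace, event_time: float, pre: float = 15.0,
                   post: float = 10.0, alignment_class: str = "reward") -> AlignedSegment:
    """Window ``[event - pre, event + post]`` re-based to the event time.

    No resampling is performed.  If the requested window extends beyond the
    trace the segment is truncated and flagged; an event outside the trace
    raises :class:`AlignmentError`.
    """
    if event_time < trace.times[0] - 1e-9 or event_time > trace.times[-1] + 1e-9:
        raise AlignmentError("alignment event outside trace support")
    lo, hi = event_time - pre, event_time + post
    truncated = lo < trace.times[0] - 1e-9 or hi > trace.times[-1] + 1e-9
    mask = trace.window(lo, hi)
    return AlignedSegment(
        rel_times=trace.times[mask] - event_time,
        values=trace.values[mask],
        rate=trace.rate,
        alignment_class=alignment_class,
        alignment_time=event_time,
        pre=pre, post=post, truncated=truncated,
        region_name=trace.region_name,
    )


#: Per-component peak-search windows, relative to the anchoring event (s).
#: The volitional component has no event of its own and is anchored to the
#: threshold crossing, searching the approach interval before it; its window
#: stops 50 ms short of the crossing because the centered 20-ms smoothing
#: filter blends the feedback-tone onset into the boundary sample.
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "go_cue": (0.0, 1.0),
    "stop_cue": (0.0, 1.0),
    "feedback": (0.0, 1.0),
    "reward": (0.0, 3.0),
    "volitional": (-2.0, -0.05),
}


@dataclass
class ComponentPeaks:
    """Per-trial peak ΔF/F per component, with the windows actually used."""

    peaks: dict[str, float | None]
    windows: dict[str, tuple[float, float]]
    truncated: set[str] = field(default_factory=set)


def extract_component_peaks(
    segment: AlignedSegment,
    trial_events: dict[str, float | None],
    windows: dict[str, tuple[float, float]] | None = None,
) -> ComponentPeaks:
    """Peak ΔF/F per component from an aligned segment.

    ``trial_events`` maps component names to event times on the segment's
    relative time base (``None`` marks an absent event -> null peak).  The
    peak for a component is the maximum of the segment within
    ``[event + w_lo, event + w_hi]``; windows that fall partly outside the
    segment are truncated and flagged, fully outside yields a null peak.
    """
    if windows is None:
        windows = DEFAULT_PEAK_WINDOWS
    peaks: dict[str, float | None] = {}
    used: dict[str, tuple[float, float]] = {}
    flagged: set[str] = set()
    for comp, ev in trial_events.items():
        w = windows.get(comp)
        if w is None:
            raise PhotometryError(f"no search window for component {comp!r}")
        if w[1] <= w[0]:
            raise PhotometryError(f"degenerate window for {comp!r}")
        if ev is None:
            peaks[comp] = None
            used[comp] = w
            continue
        lo, hi = ev + w[0], ev + w[1]
        mask = (segment.rel_times >= lo - 1e-9) & (segment.rel_times <= hi + 1e-9)
        if segment.rel_times.size and (
                lo < segment.rel_times[0] - 1e-9 or hi > segment.rel_times[-1] + 1e-9):
            flagged.add(comp)
        if not mask.any():
            peaks[comp] = None
        else:
            peaks[comp] = float(segment.values[mask].max())
        used[comp] = w
    return ComponentPeaks(peaks=peaks, windows=used, truncated=flagged)
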