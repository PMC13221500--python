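"""Session-level processing: traces + event logs -> tidy component-peak tables.

For each trial the session trace is sliced, smoothed (20-ms span / 10-ms
step), converted to ΔF/F against the cue-locked baseline, aligned to the
trial's anchor event (reward when delivered, otherwise feedback, otherwise
the threshold crossing, otherwise the cue), and searched for per-component
peaks in event-locked windows.  Withdrawal variants keep their would-be
anchor times (recorded by the engine as ground truth), so an ablated
component is measured in the same window it would have occupied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import photometry as phot
from .engine import SessionLog

__all__ = ["trial_peaks", "session_peak_table", "ground_truth_peak"]

_COMP_TO_CLASS = {
    "go_cue": "go_cue",
    "stop_cue": "stop_cue",
    "volitional": "volitional_ramp",
    "feedback": "feedback",
    "reward": "reward",
}


def _anchor(gt_anchors: dict) -> tuple[str, float]:
    for cls in ("reward", "feedback", "volitional", "go_cue"):
        if gt_anchors.get(cls) is not None:
            return cls, gt_anchors[cls]
    raise phot.AlignmentError("trial has no usable anchor event")


#: pre-cue margin included in each trial slice; F0 is taken from the 10 ms
#: immediately before cue onset (the tail of the preceding ITI, free of
#: evoked transients) and ends one smoothing half-span before the cue so
#: the centered filter cannot blend the cue onset into the baseline.
PRE_CUE_BASELINE_S = 0.03
_F0_ANCHOR_S = -0.02


def _trial_dff(log: SessionLog, i: int, region: str) -> phot.Trace:
    onset = log.trial_onsets[i]
    dur = log.trials[i].duration
    tr = log.traces[region]
    pre = PRE_CUE_BASELINE_S
    mask = tr.window(onset - pre, onset + dur - 0.5 / tr.rate)
    sliced = phot.Trace(tr.times[mask] - onset, tr.values[mask], tr.rate,
                        region_name=region)
    smoothed = phot.moving_average(sliced)
    return phot.compute_dff(smoothed, cue_time=_F0_ANCHOR_S)


def trial_peaks(log: SessionLog, i: int, region: str,
                pre: float = 15.0, post: float = 10.0,
                windows=None) -> phot.ComponentPeaks:
    """Component peaks for one trial in one region."""
    if log.traces is None:
        raise phot.PhotometryError("session was run without traces")
    gt = log.ground_truth[i]
    anchor_cls, anchor_t = _anchor(gt["anchors"])
    dff = _trial_dff(log, i, region)
    pre_eff = min(pre, anchor_t)
    seg = phot.align_to_event(dff, anchor_t, pre=pre_eff, post=post,
                              alignment_class=anchor_cls)
    rel_events = {
        comp: (gt["anchors"][comp] - anchor_t
               if gt["anchors"].get(comp) is not None else None)
        for comp in _COMP_TO_CLASS
    }
    return phot.extract_component_peaks(seg, rel_events, windows=windows)


def ground_truth_peak(log: SessionLog, i: int, region: str,
                      component: str, windows=None) -> float | None:
    """The generator's own component maximum in the component's window.

    Computed from the per-class contribution arrays the generator returned
    (ΔF/F scale, i.e. divided by the region baseline), in the same
    event-locked window the measured peak uses.  None if the component's
    anchor is absent.
    """
    gt = log.ground_truth[i]
    if gt["components"] is None:
        raise phot.PhotometryError("ground-truth components not rendered")
    if windows is None:
        windows = phot.DEFAULT_PEAK_WINDOWS
    ev = gt["anchors"].get(component)
    if ev is None:
        return None
    w = windows[component]
    comp = gt["components"][region][_COMP_TO_CLASS[component]]
    rate = log.config.rate
    t = np.arange(comp.size) / rate
    mask = (t >= ev + w[0] - 1e-9) & (t <= ev + w[1] + 1e-9)
    if not mask.any():
        return None
    baseline = 1.0
    # components are additive in fluorescence a.u.; ΔF/F divides by F0≈baseline
    return float(comp[mask].max() / baseline)


def session_peak_table(log: SessionLog, regions=None, pre: float = 15.0,
                       post: float = 10.0, windows=None) -> pd.DataFrame:
    """Tidy per-trial peak table for a session.

    Columns: mouse, day, mode, trial, trial_type, outcome, region,
    component, peak_dff, window_lo, window_hi, truncated.
    """
    if log.traces is None:
        raise phot.PhotometryError("session was run without traces")
    if regions is None:
        regions = list(log.traces)
    rows = []
    for i, trial in enumerate(log.trials):
        for region in regions:
            peaks = trial_peaks(log, i, region, pre=pre, post=post,
                                windows=windows)
            for comp, val in peaks.peaks.items():
                lo, hi = peaks.windows[comp]
                rows.append({
                    "mouse": log.mouse_id, "day": log.day,
                    "mode": log.mode.mode, "trial": i,
                    "trial_type": trial.trial_type, "outcome": trial.outcome,
                    "region": region, "component": comp,
                    "peak_dff": np.nan if val is None else val,
                    "window_lo": lo, "window_hi": hi,
                    "truncated": comp in peaks.truncated,
                })
    return pd.DataFrame(rows)
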