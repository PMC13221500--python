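"""File-based analysis: logs on disk -> peak tables and statistics report.

Mirrors the in-memory pipeline for runs that were written out by the
simulator CLI: behavioral endpoints are recomputed from the flat event
logs, component peaks from the trace CSVs plus their ground-truth
sidecars, groups are formed by manipulation mode, and each manipulated
group is tested against control with both the Student's t and the
Mann-Whitney U test (the report flags endpoints where the two disagree at
the 0.05 level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from . import photometry as phot
from .stats import compare_groups, significance_stars, InsufficientDataError

__all__ = ["load_sessions", "behavior_table", "peak_table", "group_report",
           "AnalysisError"]


class AnalysisError(ValueError):
    pass


@dataclass
class FileSession:
    """A session reconstructed from its on-disk artifacts."""

    mouse_id: str
    day: int
    mode: str
    summary: dict
    events: pd.DataFrame
    traces: dict[str, phot.Trace] | None = None
    ground_truth: dict | None = None


def load_sessions(log_dir: str | Path) -> list[FileSession]:
    log_dir = Path(log_dir)
    summaries = sorted(log_dir.glob("*_summary.json"))
    if not summaries:
        raise AnalysisError(f"no session logs found in {log_dir}")
    sessions = []
    for spath in summaries:
        stem = spath.name[: -len("_summary.json")]
        summary = vio.read_summary(spath)
        events = vio.read_event_log(log_dir / f"{stem}_events.csv")
        traces = None
        gt = None
        tpath = log_dir / f"{stem}_traces.csv"
        gpath = log_dir / f"{stem}_ground_truth.json"
        if tpath.exists() and gpath.exists():
            frame = pd.read_csv(tpath)
            rate = summary["config"]["rate"]
            traces = {c: phot.Trace(frame["time_s"].to_numpy(),
                                    frame[c].to_numpy(), rate, c)
                      for c in frame.columns if c != "time_s"}
            gt = json.loads(gpath.read_text())
        sessions.append(FileSession(
            mouse_id=summary["mouse_id"], day=summary["day"],
            mode=summary["mode"], summary=summary, events=events,
            traces=traces, ground_truth=gt))
    return sessions


def _trial_table(events: pd.DataFrame) -> pd.DataFrame:
    trials = events[events["trial_index"] >= 0]
    return (trials.groupby("trial_index")
            .agg(trial_type=("trial_type", "first"),
                 outcome=("outcome", "first"),
                 response_time_s=("response_time_s", "first"))
            .reset_index())


def behavior_table(sessions: list[FileSession]) -> pd.DataFrame:
    """Per-session behavioral endpoints recomputed from event logs."""
    rows = []
    for s in sessions:
        tt = _trial_table(s.events)
        licks = int((s.events["event_class"] == "lick").sum())

        def rate(kind):
            sub = tt[tt["trial_type"] == kind]
            return (sub["outcome"] == "success").mean() if len(sub) else np.nan

        go_rt = tt[(tt["trial_type"] == "GO") & (tt["outcome"] == "success")
                   ]["response_time_s"].dropna()
        nogo_rt = tt[(tt["trial_type"] == "NOGO")
                     & (tt["outcome"] == "failure")
                     ]["response_time_s"].dropna()
        rows.append({
            "mouse_id": s.mouse_id, "day": s.day, "mode": s.mode,
            "go_success": rate("GO"), "nogo_success": rate("NOGO"),
            "go_rt": go_rt.mean() if len(go_rt) else np.nan,
            "nogo_error_rt": nogo_rt.mean() if len(nogo_rt) else np.nan,
            "total_licks": licks,
        })
    return pd.DataFrame(rows)


def peak_table(sessions: list[FileSession], pre: float = 15.0,
               post: float = 10.0) -> pd.DataFrame:
    """Component-peak table for all sessions that carry traces."""
    rows = []
    for s in sessions:
        if s.traces is None:
            continue
        onsets = s.ground_truth["trial_onsets"]
        trials = s.ground_truth["trials"]
        tt = _trial_table(s.events).set_index("trial_index")
        first = next(iter(s.traces.values()))
        for i, (onset, gt) in enumerate(zip(onsets, trials)):
            end = (onsets[i + 1] if i + 1 < len(onsets)
                   else float(first.times[-1]) + 1.0 / first.rate)
            anchors = gt["anchors"]
            anchor = next((anchors[c] for c in
                           ("reward", "feedback", "volitional", "go_cue")
                           if anchors.get(c) is not None), None)
            if anchor is None:
                continue
            for region, tr in s.traces.items():
                # F0 from the 10 ms preceding cue onset (event-free ITI
                # tail), clear of the centered filter's half-span
                mask = tr.window(onset - 0.03, end - 0.5 / tr.rate)
                sliced = phot.Trace(tr.times[mask] - onset, tr.values[mask],
                                    tr.rate, region)
                dff = phot.compute_dff(phot.moving_average(sliced), -0.02)
                seg = phot.align_to_event(dff, anchor,
                                          pre=min(pre, anchor), post=post)
                rel = {c: (anchors[c] - anchor
                           if anchors.get(c) is not None else None)
                       for c in ("go_cue", "stop_cue", "volitional",
                                 "feedback", "reward")}
                peaks = phot.extract_component_peaks(seg, rel)
                for comp, val in peaks.peaks.items():
                    lo, hi = peaks.windows[comp]
                    rows.append({
                        "mouse": s.mouse_id, "day": s.day, "mode": s.mode,
                        "trial": i, "trial_type": tt.loc[i, "trial_type"],
                        "outcome": tt.loc[i, "outcome"], "region": region,
                        "component": comp,
                        "peak_dff": np.nan if val is None else val,
                        "window_lo": lo, "window_hi": hi,
                        "truncated": comp in peaks.truncated,
                    })
    return pd.DataFrame(rows)


_ENDPOINT_COLS = ("go_success", "nogo_success", "go_rt", "nogo_error_rt",
                  "total_licks")


def group_report(sessions: list[FileSession],
                 control: str = "control") -> dict:
    """Per-endpoint two-group statistics report keyed by endpoint name.

    Mice are averaged across their sessions first (one point per mouse);
    both tests run per contrast and disagreements at 0.05 are flagged.
    """
    behav = behavior_table(sessions)
    per_mouse = (behav.groupby(["mode", "mouse_id"])[list(_ENDPOINT_COLS)]
                 .mean().reset_index())
    modes = sorted(per_mouse["mode"].unique())
    report: dict = {"n_sessions": len(sessions), "groups": modes,
                    "endpoints": {}}
    if control not in modes or len(modes) < 2:
        return report
    ctrl = per_mouse[per_mouse["mode"] == control]
    for ep in _ENDPOINT_COLS:
        ep_entry = {}
        for mode in modes:
            if mode == control:
                continue
            grp = per_mouse[per_mouse["mode"] == mode]
            entry = {}
            try:
                for test in ("student_t", "mann_whitney_u"):
                    c = compare_groups(ep, mode, grp[ep], control,
                                       ctrl[ep], test=test)
                    entry[test] = {
                        "statistic": c.statistic, "p_value": c.p_value,
                        "stars": c.stars, "mean_group": c.mean_a,
                        "mean_control": c.mean_b,
                    }
                entry["tests_disagree"] = (
                    (entry["student_t"]["p_value"] < 0.05)
                    != (entry["mann_whitney_u"]["p_value"] < 0.05))
            except InsufficientDataError as err:
                entry = {"error": str(err)}
            ep_entry[mode] = entry
        report["endpoints"][ep] = ep_entry
    return report
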