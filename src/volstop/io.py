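"""File I/O for session logs, traces, and analysis outputs.

All formats are plain text: the event log is a flat CSV (one row per event,
plus lick rows), traces are CSV with a time column and one column per
region, and the session summary (config snapshot, seeds, threshold,
success counts) is JSON.  Every file carries the log schema version so
readers can reject incompatible inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SessionLog, TaskConfig, ThresholdRule

__all__ = [
    "SCHEMA_VERSION",
    "event_log_frame",
    "write_session",
    "read_event_log",
    "read_summary",
    "config_hash",
]

SCHEMA_VERSION = "1"


class SchemaVersionError(ValueError):
    pass


def _config_dict(config: TaskConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_hash(config: TaskConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def event_log_frame(log: SessionLog) -> pd.DataFrame:
    """Flat event table: mouse_id, day, mode, trial_index, trial_type,
    event_class, time_s (absolute session time), outcome, response_time_s.

    Licks appear as event_class="lick" rows with trial fields empty.
    """
    rows = []
    for onset, trial in zip(log.trial_onsets, log.trials):
        for cls, t in trial.events:
            rows.append({
                "mouse_id": log.mouse_id, "day": log.day,
                "mode": log.mode.mode, "trial_index": trial.trial_index,
                "trial_type": trial.trial_type, "event_class": cls,
                "time_s": round(onset + t, 6), "outcome": trial.outcome,
                "response_time_s": (np.nan if trial.response_time is None
                                    else trial.response_time),
            })
    for t in log.licks:
        rows.append({
            "mouse_id": log.mouse_id, "day": log.day, "mode": log.mode.mode,
            "trial_index": -1, "trial_type": "", "event_class": "lick",
            "time_s": round(float(t), 6), "outcome": "",
            "response_time_s": np.nan,
        })
    return pd.DataFrame(rows)


def _summary_dict(log: SessionLog) -> dict:
    cfg = _config_dict(log.config)
    return {
        "schema_version": SCHEMA_VERSION,
        "mouse_id": log.mouse_id,
        "day": log.day,
        "mode": log.mode.mode,
        "seed_entropy": log.seed_entropy,
        "threshold": log.threshold,
        "config": cfg,
        "config_hash": config_hash(log.config),
        "tags": log.tags,
        "n_trials": len(log.trials),
        "n_success": log.successes(),
        "n_go": log.presented("GO"),
        "n_go_success": log.successes("GO"),
        "n_nogo": log.presented("NOGO"),
        "n_nogo_success": log.successes("NOGO"),
        "n_licks": int(len(log.licks)),
        "max_trials_reached": log.max_trials_reached,
    }


def write_session(log: SessionLog, out_dir: str | Path,
                  stem: str | None = None) -> dict[str, Path]:
    """Write event log CSV, summary JSON and (if present) trace CSV plus a
    ground-truth sidecar JSON.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{log.mouse_id}_day{log.day}"
    paths: dict[str, Path] = {}

    events = event_log_frame(log)
    paths["events"] = out_dir / f"{stem}_events.csv"
    events.to_csv(paths["events"], index=False)

    paths["summary"] = out_dir / f"{stem}_summary.json"
    paths["summary"].write_text(
        json.dumps(_summary_dict(log), indent=1, sort_keys=True))

    if log.traces is not None:
        first = next(iter(log.traces.values()))
        frame = pd.DataFrame({"time_s": first.times})
        for region, tr in log.traces.items():
            frame[region] = tr.values
        paths["traces"] = out_dir / f"{stem}_traces.csv"
        frame.to_csv(paths["traces"], index=False, float_format="%.6f")

        sidecar = {
            "schema_version": SCHEMA_VERSION,
            "trial_onsets": [round(t, 6) for t in log.trial_onsets],
            "trials": [
                {"variant": gt["variant"], "attempt": gt["attempt"],
                 "ramp_start": gt["ramp_start"], "crossing": gt["crossing"],
                 "anchors": gt["anchors"]}
                for gt in log.ground_truth
            ],
        }
        paths["ground_truth"] = out_dir / f"{stem}_ground_truth.json"
        paths["ground_truth"].write_text(json.dumps(sidecar, indent=1))
    return paths


def read_event_log(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False,
                        na_values=[""], dtype={"trial_type": str})
    required = {"mouse_id", "day", "mode", "trial_index", "trial_type",
                "event_class", "time_s", "outcome"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaVersionError(
            f"event log {path} missing columns {sorted(missing)}")
    return frame


def read_summary(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported log schema {data.get('schema_version')!r}")
    return data
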