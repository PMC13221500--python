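"""Experiment-level summaries and recovery suites.

Reduces session logs to per-mouse behavioral endpoints (one independent
data point per mouse, averaging the design's included sessions — e.g. the
three CNO-on days of the chemogenetic design), runs the pairwise
manipulation-vs-control contrasts, and provides the simulation suites used
to validate the pipeline: type-I calibration on null experiments,
withdrawal (ablation) detection on traced sessions, and recovery of the
qualitative significance pattern programmed into the manipulation effect
tables.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import stats as vstats
from .engine import (ExperimentResult, SessionLog, TaskConfig, run_experiment,
                     run_session)
from .pipeline import session_peak_table
from .stats import GroupComparison, InsufficientDataError, compare_groups
from .synth import AgentParams, default_profiles, manipulation_mode

__all__ = [
    "ENDPOINTS",
    "EXPECTED_PATTERN",
    "session_endpoint",
    "mouse_summary_table",
    "summarize_and_compare",
    "pattern_recovery",
    "null_calibration",
    "ablation_detection",
    "peak_mouse_table",
]

ENDPOINTS = ("go_success", "nogo_success", "go_rt", "nogo_error_rt",
             "total_licks")


def session_endpoint(log: SessionLog, endpoint: str) -> float:
    """One behavioral endpoint for one session (NaN when undefined)."""
    if endpoint == "go_success":
        return (vstats.success_rate(log, "GO")
                if log.presented("GO") else np.nan)
    if endpoint == "nogo_success":
        return (vstats.success_rate(log, "NOGO")
                if log.presented("NOGO") else np.nan)
    if endpoint == "go_rt":
        rts = vstats.response_times(log, "GO", "success")
        return float(np.mean(rts)) if rts else np.nan
    if endpoint == "nogo_error_rt":
        rts = vstats.response_times(log, "NOGO", "failure")
        return float(np.mean(rts)) if rts else np.nan
    if endpoint == "total_licks":
        return float(len(log.licks))
    raise vstats.StatsError(f"unknown endpoint {endpoint!r}")


def _included(logs: list[SessionLog]) -> list[SessionLog]:
    inc = [l for l in logs if l.tags.get("include", True)]
    return inc


def mouse_summary_table(expt: ExperimentResult,
                        endpoints=ENDPOINTS) -> pd.DataFrame:
    """Per-mouse endpoint values averaged over the included sessions.

    Exactly one row per mouse per endpoint; a mouse with no session
    defining an endpoint gets NaN.
    """
    rows = []
    for gname, mice in expt.groups.items():
        for mouse_id, logs in mice.items():
            inc = _included(logs)
            for ep in endpoints:
                vals = [session_endpoint(l, ep) for l in inc]
                vals = [v for v in vals if np.isfinite(v)]
                rows.append({
                    "group": gname, "mouse": mouse_id, "endpoint": ep,
                    "value": float(np.mean(vals)) if vals else np.nan,
                    "n_sessions": len(inc),
                })
    return pd.DataFrame(rows)


def summarize_and_compare(expt: ExperimentResult, endpoint: str,
                          test: str = "student_t",
                          control: str = "control") -> dict[str, GroupComparison]:
    """Each non-control group vs control on one per-mouse endpoint."""
    table = mouse_summary_table(expt, endpoints=(endpoint,))
    if table.empty or not np.isfinite(table["value"]).any():
        raise InsufficientDataError(f"no data for endpoint {endpoint!r}")
    by_group = {g: sub["value"].to_numpy()
                for g, sub in table.groupby("group")}
    if control not in by_group:
        raise vstats.StatsError(f"control group {control!r} absent")
    out = {}
    for gname, vals in by_group.items():
        if gname == control:
            continue
        out[gname] = compare_groups(endpoint, gname, vals, control,
                                    by_group[control], test=test)
    return out


#: Qualitative significance pattern programmed into the effect tables:
#: "down"/"up" = significant in that direction vs control, "none" = null.
EXPECTED_PATTERN: dict[tuple[str, str], str] = {}
for _ep in ENDPOINTS:
    for _m in ("hM3D", "hM4D", "eNpHR_at_feedback", "eNpHR_at_cue",
               "eNpHR_at_reward"):
        EXPECTED_PATTERN[(_m, _ep)] = "none"
EXPECTED_PATTERN.update({
    ("hM3D", "go_success"): "down",
    ("hM3D", "nogo_success"): "up",
    ("hM3D", "total_licks"): "down",
    ("eNpHR_at_feedback", "go_success"): "down",
    ("eNpHR_at_feedback", "nogo_success"): "up",
    ("eNpHR_at_feedback", "go_rt"): "up",
})

_GROUP_MODE_LABEL = {
    "chemogenetic": {"hM3D": "hM3D", "hM4D": "hM4D"},
    "optogenetic_feedback": {"eNpHR": "eNpHR_at_feedback"},
    "optogenetic_cue": {"eNpHR": "eNpHR_at_cue"},
    "optogenetic_reward": {"eNpHR": "eNpHR_at_reward"},
}


def _pattern_one_rep(seed, agent, profiles, config, test) -> dict:
    cells = {}
    for design, labels in _GROUP_MODE_LABEL.items():
        expt = run_experiment(design, seed.spawn(1)[0], agent=agent,
                              profiles=profiles, config=config,
                              synth_traces=False)
        for ep in ENDPOINTS:
            try:
                comps = summarize_and_compare(expt, ep, test=test)
            except InsufficientDataError:
                for g, label in labels.items():
                    cells[(label, ep)] = None
                continue
            for g, label in labels.items():
                cmp_ = comps[g]
                direction = ("up" if cmp_.mean_a > cmp_.mean_b else "down")
                sig = cmp_.p_value < 0.05
                cells[(label, ep)] = (sig, direction)
    return cells


def pattern_recovery(n_reps: int = 100, seed: int = 0,
                     agent: AgentParams | None = None,
                     test: str = "student_t",
                     config: TaskConfig | None = None) -> pd.DataFrame:
    """Fraction of replicates reproducing each expected significance cell.

    Each replicate runs the full chemogenetic and the three optogenetic
    designs at the study sizes (6/6/6 and 6/7 mice, 6- and 3-day designs,
    50-success sessions) on the behavior-only path, compares each
    manipulation group with its control on every behavioral endpoint, and
    scores each (mode, endpoint) cell: an expected "up"/"down" cell is
    correct when significant (p < 0.05) in that direction, an expected
    "none" cell when non-significant.
    """
    agent = agent or AgentParams()
    profiles = default_profiles()
    config = config or TaskConfig()
    root = np.random.SeedSequence(seed)
    reps = [_pattern_one_rep(child, agent, profiles, config, test)
            for child in root.spawn(n_reps)]
    rows = []
    for (mode, ep), expected in EXPECTED_PATTERN.items():
        correct = sig = 0
        for cells in reps:
            got = cells.get((mode, ep))
            if got is None:
                continue
            is_sig, direction = got
            sig += is_sig
            if expected == "none":
                correct += not is_sig
            else:
                correct += is_sig and direction == expected
        rows.append({
            "mode": mode, "endpoint": ep, "expected": expected,
            "n_reps": len(reps), "frac_significant": sig / len(reps),
            "frac_correct": correct / len(reps),
        })
    return pd.DataFrame(rows)


def null_calibration(n_reps: int = 1000, seed: int = 0,
                     endpoint: str = "go_success", alpha: float = 0.05,
                     n_per_group: int = 6,
                     config: TaskConfig | None = None) -> dict:
    """Type-I error of both tests on null (control vs control) experiments.

    Each replicate simulates two independent groups of control mice (one
    50-success session each, behavior-only) and tests the per-mouse
    endpoint at level alpha.  Returns rejection rates and the binomial SE.
    """
    agent = AgentParams()
    profiles = default_profiles()
    config = config or TaskConfig()
    mode = manipulation_mode("control")
    root = np.random.SeedSequence(seed)
    rej = {"student_t": 0, "mann_whitney_u": 0}
    for child in root.spawn(n_reps):
        seeds = child.spawn(2 * n_per_group)
        vals = []
        for s in seeds:
            log = run_session(agent, profiles, config, mode, s,
                              synth_traces=False)
            vals.append(session_endpoint(log, endpoint))
        a, b = vals[:n_per_group], vals[n_per_group:]
        for test in rej:
            cmp_ = compare_groups(endpoint, "a", a, "b", b, test=test)
            rej[test] += cmp_.p_value < alpha
    return {
        "n_reps": n_reps, "alpha": alpha,
        "se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
        "rates": {t: r / n_reps for t, r in rej.items()},
    }


_WITHDRAWN_COMPONENT = {
    "GO_no_cue": "go_cue",
    "GO_no_feedback": "feedback",
    "GO_no_reward": "reward",
}


def peak_mouse_table(logs_by_mouse: dict[str, list[SessionLog]],
                     region: str, component: str,
                     outcome: str = "success") -> list[float]:
    """Per-mouse mean component peak (ΔF/F) over a mouse's success trials."""
    out = []
    for mouse, logs in logs_by_mouse.items():
        vals = []
        for log in logs:
            table = session_peak_table(log, regions=[region])
            sub = table[(table["component"] == component)
                        & (table["outcome"] == outcome)
                        & (~table["truncated"])]
            vals.extend(sub["peak_dff"].dropna().tolist())
        out.append(float(np.mean(vals)) if vals else np.nan)
    return out


def ablation_detection(n_reps: int = 100, seed: int = 0,
                       n_per_group: int = 6, n_success: int = 12,
                       alpha: float = 0.05, region: str = "M1") -> dict:
    """Power of the group comparison to detect a withdrawn component.

    Each replicate simulates a control group running standard GO-only
    sessions and one group per withdrawal variant (cue, feedback, or reward
    omitted), with traces at default noise; the per-mouse mean peak of the
    withdrawn component is compared between groups (Student's t, p < alpha,
    reduction direction).  Returns the detection fraction per variant.
    """
    agent = AgentParams()
    profiles = default_profiles()
    config = TaskConfig(p_go=1.0, n_success_target=n_success)
    mode = manipulation_mode("control")
    root = np.random.SeedSequence(seed)
    hits = {v: 0 for v in _WITHDRAWN_COMPONENT}
    for child in root.spawn(n_reps):
        seeds = iter(child.spawn(n_per_group * (1 + len(_WITHDRAWN_COMPONENT))))
        control = {}
        for m in range(n_per_group):
            control[f"c{m}"] = [run_session(
                agent, profiles, config, mode, next(seeds),
                mouse_id=f"c{m}", synth_traces=True, regions=(region,))]
        for variant, comp in _WITHDRAWN_COMPONENT.items():
            ablated = {}
            for m in range(n_per_group):
                ablated[f"a{m}"] = [run_session(
                    agent, profiles, config, mode, next(seeds),
                    mouse_id=f"a{m}", synth_traces=True, regions=(region,),
                    go_variant=variant)]
            va = peak_mouse_table(ablated, region, comp)
            vc = peak_mouse_table(control, region, comp)
            cmp_ = compare_groups(comp, "ablated", va, "control", vc)
            if cmp_.p_value < alpha and cmp_.mean_a < cmp_.mean_b:
                hits[variant] += 1
    return {"n_reps": n_reps,
            "detect_fraction": {v: h / n_reps for v, h in hits.items()}}
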