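"""Seeded fixture generation for tests and demos.

``smoke`` builds in seconds: one traced session plus a miniature
chemogenetic design.  ``study`` reproduces the study's group structure
(control/hM3D/hM4D at n=6/6/6; control/eNpHR at n=6/7) at reduced
per-session trial counts, behavior-only.  Every fixture directory carries
the generating config for provenance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from . import io as vio
from .config import RunConfig, dump_config
from .engine import TaskConfig, run_experiment, run_session
from .synth import AgentParams, default_profiles, manipulation_mode

__all__ = ["make_fixtures"]


def _write_experiment(expt, out_dir: Path) -> int:
    n = 0
    for mice in expt.groups.values():
        for logs in mice.values():
            for log in logs:
                vio.write_session(log, out_dir)
                n += 1
    return n


def make_fixtures(scale: str, out_dir: str | Path,
                  seed: int = 0) -> dict[str, Path]:
    if scale not in ("smoke", "study"):
        raise ValueError(f"unknown fixture scale {scale!r}")
    out_dir = Path(out_dir)
    agent = AgentParams()
    profiles = default_profiles()
    paths: dict[str, Path] = {}

    if scale == "smoke":
        cfg = TaskConfig(n_success_target=5)
        sess_dir = out_dir / "session"
        log = run_session(agent, profiles, cfg, manipulation_mode("control"),
                          seed, mouse_id="smoke0", synth_traces=True)
        vio.write_session(log, sess_dir)
        paths["session"] = sess_dir

        chemo_dir = out_dir / "chemo_mini"
        expt = run_experiment(
            "chemogenetic", seed + 1, agent=agent, profiles=profiles,
            config=TaskConfig(n_success_target=8),
            n_mice={"control": 2, "hM3D": 2, "hM4D": 2}, days=2,
            synth_traces=False)
        _write_experiment(expt, chemo_dir)
        paths["chemo_mini"] = chemo_dir
        run_cfg = RunConfig(task=cfg, seed=seed,
                            output_dir=str(sess_dir))
    else:
        cfg = TaskConfig(n_success_target=15)
        chemo_dir = out_dir / "chemogenetic"
        expt = run_experiment("chemogenetic", seed, agent=agent,
                              profiles=profiles, config=cfg,
                              synth_traces=False)
        _write_experiment(expt, chemo_dir)
        paths["chemogenetic"] = chemo_dir
        for design in ("optogenetic_feedback", "optogenetic_cue",
                       "optogenetic_reward"):
            d = out_dir / design
            expt = run_experiment(design, seed + 1, agent=agent,
                                  profiles=profiles, config=cfg,
                                  synth_traces=False)
            _write_experiment(expt, d)
            paths[design] = d
        run_cfg = RunConfig(task=cfg, seed=seed, design="chemogenetic",
                            synth_traces=False,
                            output_dir=str(chemo_dir))

    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_path = out_dir / "fixture_config.yaml"
    cfg_path.write_text(dump_config(run_cfg))
    paths["config"] = cfg_path
    return paths
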