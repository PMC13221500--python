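"""Structured run configuration (YAML) for simulations.

A :class:`RunConfig` bundles everything a simulation needs — task
constants, agent parameters, region profiles, manipulation mode, design
and seed — in one human-readable document that round-trips losslessly
through serialize/parse.  Unknown keys are rejected with a clear error so
experiment definitions stay reviewable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import DESIGNS, TaskConfig, ThresholdRule
from .synth import (EVENT_CLASSES, AgentParams, ManipulationMode,
                    RegionProfile, TransientKernel, default_profiles,
                    manipulation_mode, MODE_NAMES)

__all__ = ["RunConfig", "ConfigFileError", "load_config", "dump_config"]

CONFIG_VERSION = "1"


class ConfigFileError(ValueError):
    pass


def _check_keys(section: str, data: dict, allowed) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigFileError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    """Complete, versioned description of one simulation run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    profiles: dict[str, RegionProfile] = field(default_factory=default_profiles)
    mode: str = "control"
    design: str | None = None
    seed: int = 0
    days: int | None = None
    synth_traces: bool = True
    regions: tuple[str, ...] = ("M1", "GPe", "STN")
    output_dir: str = "results/session"
    version: str = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.mode not in MODE_NAMES:
            raise ConfigFileError(f"unknown manipulation mode {self.mode!r}")
        if self.design is not None and self.design not in DESIGNS:
            raise ConfigFileError(f"unknown design {self.design!r}")
        missing = [r for r in self.regions if r not in self.profiles]
        if missing:
            raise ConfigFileError(f"no profile for region(s) {missing}")

    @property
    def manipulation(self) -> ManipulationMode:
        return manipulation_mode(self.mode)


def _task_to_dict(task: TaskConfig) -> dict:
    d = dataclasses.asdict(task)
    return d


def _task_from_dict(data: dict) -> TaskConfig:
    fields = {f.name for f in dataclasses.fields(TaskConfig)}
    _check_keys("task", data, fields)
    data = dict(data)
    if "threshold_rule" in data:
        tr = data["threshold_rule"]
        _check_keys("task.threshold_rule", tr,
                    {f.name for f in dataclasses.fields(ThresholdRule)})
        data["threshold_rule"] = ThresholdRule(**tr)
    return TaskConfig(**data)


def _agent_from_dict(data: dict) -> AgentParams:
    fields = {f.name for f in dataclasses.fields(AgentParams)}
    _check_keys("agent", data, fields)
    return AgentParams(**data)


def _profiles_to_dict(profiles: dict[str, RegionProfile]) -> dict:
    out = {}
    for name, prof in profiles.items():
        out[name] = {
            "baseline_F": prof.baseline_F,
            "noise_sd": prof.noise_sd,
            "drift_per_s": prof.drift_per_s,
            "kernels": {
                cls: {"amplitude": k.amplitude, "rise_tau": k.rise_tau,
                      "decay_tau": k.decay_tau}
                for cls, k in prof.kernels.items()
            },
        }
    return out


def _profiles_from_dict(data: dict) -> dict[str, RegionProfile]:
    out = {}
    for name, pd_ in data.items():
        _check_keys(f"profiles.{name}", pd_,
                    {"baseline_F", "noise_sd", "drift_per_s", "kernels"})
        kernels = {}
        for cls, kd in pd_.get("kernels", {}).items():
            if cls not in EVENT_CLASSES:
                raise ConfigFileError(f"unknown kernel class {cls!r}")
            _check_keys(f"profiles.{name}.kernels.{cls}", kd,
                        {"amplitude", "rise_tau", "decay_tau"})
            kernels[cls] = TransientKernel(**kd)
        out[name] = RegionProfile(
            region_name=name,
            baseline_F=pd_.get("baseline_F", 1.0),
            noise_sd=pd_.get("noise_sd", 0.0),
            kernels=kernels,
            drift_per_s=pd_.get("drift_per_s", 0.0),
        )
    return out


_TOP_KEYS = ("version", "task", "agent", "profiles", "mode", "design",
             "seed", "days", "synth_traces", "regions", "output_dir")


def dump_config(cfg: RunConfig) -> str:
    doc = {
        "version": cfg.version,
        "task": _task_to_dict(cfg.task),
        "agent": dataclasses.asdict(cfg.agent),
        "profiles": _profiles_to_dict(cfg.profiles),
        "mode": cfg.mode,
        "design": cfg.design,
        "seed": cfg.seed,
        "days": cfg.days,
        "synth_traces": cfg.synth_traces,
        "regions": list(cfg.regions),
        "output_dir": cfg.output_dir,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_config(source: str | Path) -> RunConfig:
    """Parse a YAML config (path or string), rejecting unknown keys."""
    text = (Path(source).read_text()
            if isinstance(source, Path) or "\n" not in str(source)
            and Path(str(source)).exists()
            else str(source))
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigFileError("config document must be a mapping")
    _check_keys("<top level>", data, _TOP_KEYS)
    version = str(data.get("version", CONFIG_VERSION))
    if version != CONFIG_VERSION:
        raise ConfigFileError(f"unsupported config version {version!r}")
    return RunConfig(
        task=_task_from_dict(data.get("task", {})),
        agent=_agent_from_dict(data.get("agent", {})),
        profiles=(_profiles_from_dict(data["profiles"])
                  if "profiles" in data else default_profiles()),
        mode=data.get("mode", "control"),
        design=data.get("design"),
        seed=int(data.get("seed", 0)),
        days=data.get("days"),
        synth_traces=bool(data.get("synth_traces", True)),
        regions=tuple(data.get("regions", ("M1", "GPe", "STN"))),
        output_dir=data.get("output_dir", "results/session"),
        version=version,
    )
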