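"""Declarative run configuration (YAML) for the pipeline CLI.

One file holds the calibration, classifier thresholds, role map,
interpolation and quality settings, and the seed.  Unknown keys are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .events import ClassifierThresholds
from .traj_io import DICHOTOMOUS, NO_CHOICE, ROLES, CalibrationSpec


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    roles: dict = field(default_factory=dict)
    design: str = NO_CHOICE
    max_gap_s: float = 0.5
    quality_threshold: float = 0.80
    quality_aggregate: str = "min"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in (DICHOTOMOUS, NO_CHOICE):
            raise ConfigError(f"unknown design {self.design!r}")
        for ind, role in self.roles.items():
            if role not in ROLES:
                raise ConfigError(f"unknown role {role!r} for individual {ind!r}")
        if not 0 <= self.quality_threshold <= 1:
            raise ConfigError("quality_threshold must be in [0, 1]")


def _build(cls, payload: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    if "glide_speed_pcts" in payload:
        payload = {**payload, "glide_speed_pcts": tuple(payload["glide_speed_pcts"])}
    return cls(**payload)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {
        "calibration", "thresholds", "roles", "design",
        "max_gap_s", "quality_threshold", "quality_aggregate", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    cal = _build(CalibrationSpec, raw.get("calibration", {}) or {}, "calibration")
    thr = _build(ClassifierThresholds, raw.get("thresholds", {}) or {}, "thresholds")
    return RunConfig(
        calibration=cal,
        thresholds=thr,
        roles={str(k): v for k, v in (raw.get("roles", {}) or {}).items()},
        design=raw.get("design", NO_CHOICE),
        max_gap_s=float(raw.get("max_gap_s", 0.5)),
        quality_threshold=float(raw.get("quality_threshold", 0.80)),
        quality_aggregate=raw.get("quality_aggregate", "min"),
        seed=int(raw.get("seed", 0)),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration next to the outputs."""
    payload = {
        "calibration": dataclasses.asdict(cfg.calibration),
        "thresholds": {
            **dataclasses.asdict(cfg.thresholds),
            "glide_speed_pcts": list(cfg.thresholds.glide_speed_pcts),
        },
        "roles": dict(cfg.roles),
        "design": cfg.design,
        "max_gap_s": cfg.max_gap_s,
        "quality_threshold": cfg.quality_threshold,
        "quality_aggregate": cfg.quality_aggregate,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
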