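"""Structured study configuration with YAML round-tripping.

A :class:`StudyConfig` fully determines a synthetic study: cohort size,
seed, paradigm geometry, HDR/noise/motion parameters, filter settings and
evaluation knobs.  Validation errors name the offending key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .params import (
    DEFAULT_RATE,
    FilterSettings,
    HdrParams,
    MotionParams,
    NoiseParams,
)

_TUPLE_FIELDS = {"cardiac", "respiration", "mayer", "drift", "wavelengths",
                 "dpf"}


@dataclass
class StudyConfig:
    n_participants: int = 20
    seed: int = 0
    rate: float = DEFAULT_RATE
    n_task: int = 9
    n_rest: int = 9
    trial_dur: float = 30.0
    fixation_dur: float = 30.0
    hdr: HdrParams = field(default_factory=HdrParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    motion_restricted: MotionParams = field(default_factory=MotionParams.none)
    motion_unrestricted: MotionParams = field(default_factory=MotionParams)
    filters: FilterSettings = field(default_factory=FilterSettings)
    k: int = 9
    alpha: float = 0.05
    chance: float = 0.5
    window_duration: float | None = None
    participant_variability: bool = True
    permute_labels: bool = False
    stride: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants: must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate: must be positive")


_NESTED = {
    "hdr": HdrParams,
    "noise": NoiseParams,
    "motion_restricted": MotionParams,
    "motion_unrestricted": MotionParams,
    "filters": FilterSettings,
}


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) at {path}: "
            + ", ".join(f"{path}.{k}" for k in sorted(unknown))
        )
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path}: {exc}") from exc


def config_from_dict(data: dict) -> StudyConfig:
    if "seed" not in data:
        raise ValueError("config must set 'seed'")
    data = dict(data)
    for key, cls in _NESTED.items():
        if key in data:
            if not isinstance(data[key], dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            data[key] = _build(cls, data[key], key)
    return _build(StudyConfig, data, "study")


def config_to_dict(config: StudyConfig) -> dict:
    out = dataclasses.asdict(config)

    def tuples_to_lists(obj):
        if isinstance(obj, dict):
            return {k: tuples_to_lists(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return tuples_to_lists(out)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return config_from_dict(data)


def save_config(config: StudyConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False)
    )
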