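"""Run configuration: every analysis constant in one place, YAML-loadable.

Defaults reproduce the study's Methods constants exactly: 7.5 deg face
radius, 10x20 cm hand box, 40x60 cm body box, 10 cm cubes, 5 cm start
cube, 5 % onset fraction, 100 ms anticipatory and 3000 ms slow SRT
bounds, and the 0.90 calibration-validity cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .simulate import SimConfig

__all__ = ["AoiConfig", "EventConfig", "SrtBounds", "StatsConfig", "RunConfig"]


@dataclass
class AoiConfig:
    face_radius_deg: float = 7.5
    hand_length_m: float = 0.20
    hand_cross_m: float = 0.10
    body_size_m: tuple = (0.40, 0.60, 0.15)
    cube_size_m: float = 0.10
    start_size_m: float = 0.05
    cube_spacing_m: float = 0.30


@dataclass
class EventConfig:
    onset_fraction: float = 0.05
    speed_mode: str = "projected"  # or 'magnitude'
    min_look_duration_s: float = 0.05
    gap_bridge_s: float = 0.05
    arrival_radius_m: float = 0.10


@dataclass
class SrtBounds:
    anticipatory_ms: float = 100.0
    too_slow_ms: float = 3000.0


@dataclass
class StatsConfig:
    transform: str = "auto"  # auto | sqrt | log10 | identity
    alpha: float = 0.05
    strata: tuple = ("all", "overt", "not_overt")


@dataclass
class RunConfig:
    aoi: AoiConfig = field(default_factory=AoiConfig)
    events: EventConfig = field(default_factory=EventConfig)
    srt: SrtBounds = field(default_factory=SrtBounds)
    stats: StatsConfig = field(default_factory=StatsConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    validity_cutoff: float = 0.90
    face_after_nontarget: str = "incongruent"
    overt_window_s: float = 0.0
    eye_contact_min_overlap_s: float = 1.0 / 60.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = {}
        sections = {"aoi": AoiConfig, "events": EventConfig, "srt": SrtBounds,
                    "stats": StatsConfig, "sim": SimConfig}
        for key, val in raw.items():
            if key in sections:
                known = {f.name for f in dataclasses.fields(sections[key])}
                bad = set(val) - known
                if bad:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(bad)}")
                val = {k: tuple(v) if isinstance(v, list) else v for k, v in val.items()}
                kw[key] = sections[key](**val)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kw[key] = raw[key]
            else:
                raise ValueError(f"unknown config key {key!r}")
        cfg = cls(**kw)
        cfg.sim.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
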