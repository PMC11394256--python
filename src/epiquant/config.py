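"""Pipeline configuration: one nested dataclass tree with YAML loading.

All tunable defaults of every stage live here; unknown keys in a config
file are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .separation import HDAB_DAB, HDAB_HEMATOXYLIN


@dataclass
class NormalizationConfig:
    enabled: bool = True
    #: path to a reference image, a (mean, std) pair of 3-vectors, or None
    #: for the bundled synthetic reference
    reference: object = None


@dataclass
class StainsConfig:
    h_vector: list = field(default_factory=lambda: HDAB_HEMATOXYLIN.tolist())
    dab_vector: list = field(default_factory=lambda: HDAB_DAB.tolist())
    background: float = 255.0


@dataclass
class MaskConfig:
    se_radius: int = 15
    min_tissue_fraction: float = 0.005


@dataclass
class RotationConfig:
    enabled: bool = True
    angle_min: float = 1.0
    angle_max: float = 180.0
    angle_step: float = 0.1
    coarse_to_fine: bool = False
    margin_px: int = 5


@dataclass
class GateConfig:
    pixel_threshold: float = 153.0
    ap_cutoff: float = 0.6


@dataclass
class SegmentConfig:
    k_min: int = 1
    k_max: int = 3
    seed: int = 0
    n_init: int = 5
    max_iter: int = 300


@dataclass
class IOConfig:
    out_dir: object = None
    log_level: str = "INFO"


@dataclass
class PipelineConfig:
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    stains: StainsConfig = field(default_factory=StainsConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    rotation: RotationConfig = field(default_factory=RotationConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    io: IOConfig = field(default_factory=IOConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from nested dicts, rejecting unknown keys."""
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, values in (data or {}).items():
            if section not in sections:
                raise ValueError(f"unknown config section: {section!r}")
            sub = getattr(cfg, section)
            known = {f.name for f in dataclasses.fields(sub)}
            for key, val in (values or {}).items():
                if key not in known:
                    raise ValueError(f"unknown config key: {section}.{key}")
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
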