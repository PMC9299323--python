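"""Pipeline configuration: flat dotted keys, YAML-loadable, echoed into reports."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .scf import SCFParams

__all__ = ["PartitionParams", "NoiseParams", "SSIParams", "PipelineConfig"]


@dataclass
class PartitionParams:
    low_pct: float = 10.0
    high_pct: float = 70.0
    erosion_px: int = 7
    erosion_shape: str = "square"


@dataclass
class NoiseParams:
    roi_size_px: int = 21
    n_rois: int = 5
    seed: int = 20220720


@dataclass
class SSIParams:
    coef_a: float = 6.1398
    coef_b: float = 4.2813


@dataclass
class PipelineConfig:
    scf: SCFParams = field(default_factory=SCFParams)
    partition: PartitionParams = field(default_factory=PartitionParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    ssi: SSIParams = field(default_factory=SSIParams)

    def to_flat_dict(self) -> dict[str, Any]:
        flat: dict[str, Any] = {}
        for section, params in (("scf", self.scf), ("partition", self.partition),
                                ("noise", self.noise), ("ssi", self.ssi)):
            for k, v in asdict(params).items():
                flat[f"{section}.{k}"] = v
        return flat

    @classmethod
    def from_flat_dict(cls, flat: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        sections = {"scf": cfg.scf, "partition": cfg.partition,
                    "noise": cfg.noise, "ssi": cfg.ssi}
        for key, value in flat.items():
            section, _, name = key.partition(".")
            if section not in sections or not hasattr(sections[section], name):
                raise KeyError(f"unknown config key: {key}")
            setattr(sections[section], name, value)
        # re-validate SCF params
        cfg.scf.__post_init__()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict[str, Any] = {}
        for k, v in data.items():
            if isinstance(v, dict):  # nested sections are flattened
                for kk, vv in v.items():
                    flat[f"{k}.{kk}"] = vv
            else:
                flat[k] = v
        return cls.from_flat_dict(flat)
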