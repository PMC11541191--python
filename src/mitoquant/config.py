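"""Declarative pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
import datetime
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .histanalysis import FIXED_XMAX_PROCESSED

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full simulate-and-analyse run."""

    seed: int = 1
    n_replicates: int = 5
    subtract_fraction: float = 0.12
    rl_iterations: int = 20
    deconvolve: bool = True
    threshold_algorithm: str = "isodata"
    histogram_mode: str = "relative"
    fixed_x_max: float = FIXED_XMAX_PROCESSED
    n_timepoints: int = 13
    interval_s: float = 60.0
    decay_rate_per_min: float = 0.0175
    bleedthrough_fraction: float = 0.08
    fluctuation_sd: float = 0.05
    save_intermediates: bool = True
    provenance: dict = field(default_factory=dict)

    def with_provenance(self) -> "PipelineConfig":
        self.provenance = {
            "package_version": __version__,
            "python": platform.python_version(),
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        return self

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
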