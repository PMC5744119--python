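"""Run configuration: one YAML-loadable object holding every threshold."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    species_code: str = "Tat"
    triage_evalue_max: float = 1e-4
    match_tolerance: float = 1.0
    filter_tolerance_mono: float = 0.02
    filter_tolerance_average: float = 0.5
    psm_score_min: float = 25.0
    psm_fragments_min: int = 2
    seed: int = 0
    helix_angle_degrees: float = 100.0

    def __post_init__(self) -> None:
        if len(self.species_code) != 3 or not self.species_code[0].isupper():
            raise ValueError("species_code must be 3 letters, first uppercase")
        for name in (
            "triage_evalue_max",
            "match_tolerance",
            "filter_tolerance_mono",
            "filter_tolerance_average",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def filter_tolerance(self) -> dict[str, float]:
        return {
            "mono": self.filter_tolerance_mono,
            "average": self.filter_tolerance_average,
        }
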