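"""Helical-wheel physicochemical descriptors for host-defense peptides.

Cationic amphipathic venom peptides (the non-disulfide-bound families)
are profiled the way helical-wheel servers do it: mean hydrophobicity
<H> on the Fauchere-Pliska scale, the Eisenberg hydrophobic moment

    muH = (1/N) * | sum_n H_n * exp(i * n * delta) |,   delta = 100 deg

for an ideal alpha-helix, and a formal net charge (#R + #K) - (#D + #E)
with His and the termini contributing nothing.  The no-termini charge
convention is recorded in the profile metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from .chem import validate_sequence

__all__ = [
    "HydrophobicityScale",
    "PhyschemProfile",
    "fauchere_pliska",
    "net_charge",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "physchem_profile",
]

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [aa for aa in _STANDARD_AA if aa not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} misses residues {missing}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


_FP_SCALE: Optional[HydrophobicityScale] = None


def fauchere_pliska() -> HydrophobicityScale:
    """The default (octanol/water) scale, loaded from packaged data."""
    global _FP_SCALE
    if _FP_SCALE is None:
        values = {}
        ref = resources.files("venomics.data").joinpath("fauchere_pliska.tsv")
        with ref.open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("residue"):
                    continue
                aa, val = line.split("\t")
                values[aa] = float(val)
        _FP_SCALE = HydrophobicityScale("Fauchere-Pliska", values)
    return _FP_SCALE


def net_charge(sequence: str) -> int:
    """Formal charge at neutral pH, helical-wheel convention: Arg/Lys +1,
    Asp/Glu -1, His and both termini 0."""
    validate_sequence(sequence)
    return (
        sequence.count("R")
        + sequence.count("K")
        - sequence.count("D")
        - sequence.count("E")
    )


def mean_hydrophobicity(
    sequence: str, scale: Optional[HydrophobicityScale] = None
) -> float:
    validate_sequence(sequence)
    scale = scale or fauchere_pliska()
    return sum(scale[aa] for aa in sequence) / len(sequence)


def hydrophobic_moment(
    sequence: str,
    scale: Optional[HydrophobicityScale] = None,
    angle_degrees: float = 100.0,
) -> float:
    """First Fourier mode of the hydrophobicity profile at the helical
    periodicity (100 deg/residue for an alpha-helix; adjust for 3-10 or
    pi helices), normalised per residue."""
    validate_sequence(sequence)
    scale = scale or fauchere_pliska()
    delta = math.radians(angle_degrees)
    sin_sum = sum(
        scale[aa] * math.sin((n + 1) * delta) for n, aa in enumerate(sequence)
    )
    cos_sum = sum(
        scale[aa] * math.cos((n + 1) * delta) for n, aa in enumerate(sequence)
    )
    return math.hypot(sin_sum, cos_sum) / len(sequence)


@dataclass(frozen=True)
class PhyschemProfile:
    length: int
    mean_hydrophobicity: float  # 3 decimals
    hydrophobic_moment: float  # 3 decimals
    net_charge: int
    charge_convention: str = "no-termini"


def physchem_profile(
    sequence: str,
    scale: Optional[HydrophobicityScale] = None,
    angle_degrees: float = 100.0,
) -> PhyschemProfile:
    """Length, <H>, muH (both to 3 decimals) and net charge for one
    mature peptide."""
    return PhyschemProfile(
        length=len(sequence),
        mean_hydrophobicity=round(mean_hydrophobicity(sequence, scale), 3),
        hydrophobic_moment=round(
            hydrophobic_moment(sequence, scale, angle_degrees), 3
        ),
        net_charge=net_charge(sequence),
    )
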