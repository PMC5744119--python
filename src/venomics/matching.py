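"""Matching theoretical mature-peptide masses against the curated fingerprint.

Each predicted mature peptide carries a theoretical mass on one or both
scales (monoisotopic / average).  The comparison scale follows the same
3000 Da rule the fingerprint uses, and a theoretical entry is only ever
compared against fingerprint peaks of its own kind: pairing a monoisotopic
prediction with an average experimental mass (or vice versa) would build a
systematic ~0.6 Da/kDa bias into every delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .fingerprint import Fingerprint, MassPeak, mass_kind_for

__all__ = [
    "TheoreticalEntry",
    "MassMatch",
    "DEFAULT_MATCH_TOLERANCE",
    "select_mass_kind",
    "match_masses",
    "reference_theoretical_entries",
]

#: the largest credible intact-mass agreement; exposed on the CLI
DEFAULT_MATCH_TOLERANCE = 1.0


def select_mass_kind(mass: float) -> str:
    """'mono' strictly below 3000 Da, 'average' at or above (the boundary
    itself is average, consistent with the fingerprint kind rule)."""
    return mass_kind_for(mass)


@dataclass(frozen=True)
class TheoreticalEntry:
    """Theoretical mass of a predicted mature peptide.

    Either scale may be absent (published tables often print only the
    kind-selected value); when both are present monoisotopic < average.
    """

    peptide_id: str
    monoisotopic_mass: Optional[float] = None
    average_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass is None and self.average_mass is None:
            raise ValueError(f"{self.peptide_id}: no mass given")
        for m in (self.monoisotopic_mass, self.average_mass):
            if m is not None and m <= 0:
                raise ValueError(f"{self.peptide_id}: non-positive mass {m}")
        if (
            self.monoisotopic_mass is not None
            and self.average_mass is not None
            and not self.monoisotopic_mass < self.average_mass
        ):
            raise ValueError(
                f"{self.peptide_id}: monoisotopic must be below average"
            )

    @property
    def selected_kind(self) -> str:
        anchor = (
            self.average_mass
            if self.average_mass is not None
            else self.monoisotopic_mass
        )
        kind = select_mass_kind(anchor)
        # honour whichever scale is actually available
        if kind == "mono" and self.monoisotopic_mass is None:
            kind = "average"
        elif kind == "average" and self.average_mass is None:
            kind = "mono"
        return kind

    def mass(self, kind: str) -> float:
        value = self.monoisotopic_mass if kind == "mono" else self.average_mass
        if value is None:
            raise ValueError(f"{self.peptide_id}: no {kind} mass")
        return value


@dataclass(frozen=True)
class MassMatch:
    peptide_id: str
    theoretical_mass: float
    experimental_mass: float
    rt_bin: tuple[float, float]
    delta: float  # theoretical - experimental, signed


def match_masses(
    theoreticals: Sequence[TheoreticalEntry],
    fingerprint: Fingerprint,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> list[MassMatch]:
    """Nearest-peak-within-tolerance pairing, kind-restricted.

    Each theoretical entry yields at most one match (its nearest same-kind
    peak within ``tolerance``; ties broken toward smaller \\|delta\\|, then
    lower peak mass).  A peak may serve several entries -- isobaric
    peptides exist and intact masses carry no exclusivity claim.  Output
    is sorted by peptide_id.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[MassMatch] = []
    for entry in sorted(theoreticals, key=lambda e: e.peptide_id):
        kind = entry.selected_kind
        theo = entry.mass(kind)
        best: Optional[MassPeak] = None
        best_key: Optional[tuple[float, float]] = None
        for peak in fingerprint.peaks:
            if peak.mass_kind != kind:
                continue
            dist = abs(theo - peak.mass)
            if dist > tolerance:
                continue
            key = (dist, peak.mass)
            if best_key is None or key < best_key:
                best, best_key = peak, key
        if best is not None:
            matches.append(
                MassMatch(
                    peptide_id=entry.peptide_id,
                    theoretical_mass=theo,
                    experimental_mass=best.mass,
                    rt_bin=best.rt_bin,
                    delta=theo - best.mass,
                )
            )
    return matches


def reference_theoretical_entries() -> list[TheoreticalEntry]:
    """The packaged transcriptome-derived theoretical masses that were
    searched against the reference fingerprint (all above 3000 Da, hence
    average-kind)."""
    import pandas as pd

    ref = resources.files("venomics.data").joinpath("tatrox_theoretical.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for _, row in df.iterrows():
        m = float(row["theoretical_mass"])
        if select_mass_kind(m) == "mono":
            entries.append(TheoreticalEntry(row["peptide_id"], monoisotopic_mass=m))
        else:
            entries.append(TheoreticalEntry(row["peptide_id"], average_mass=m))
    return entries
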