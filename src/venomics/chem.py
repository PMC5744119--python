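"""Peptide mass arithmetic and precursor bookkeeping.

Masses are computed on two scales: monoisotopic (most-abundant isotopes)
for small peptides, and average (isotope-abundance-weighted) for larger
ones, mirroring the convention of intact-mass venom fingerprints where
deconvolution reports monoisotopic [M] below ~3 kDa and average [M] above.

Residue and water masses are derived from pyteomics' elemental tables, so
the default theoretical mass of a plain sequence reproduces ProtParam-style
output (free termini, free cysteines).  Post-translational corrections that
matter for venom peptides -- C-terminal alpha-amidation and disulfide
bridges -- are opt-in flags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

from pyteomics import mass as _pmass

__all__ = [
    "STANDARD_AA",
    "AminoAcidMassTable",
    "PeptideMassResult",
    "PrecursorModel",
    "AmidationCall",
    "peptide_mass",
    "detect_amidation",
    "percent_identity",
    "MOD_DELTAS",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: modification deltas in Da as (monoisotopic, average); plain atomic-mass
#: arithmetic (e.g. amidation = -OH +NH2, disulfide = -2H per bond).
MOD_DELTAS: dict[str, tuple[float, float]] = {
    "amidation": (-0.98402, -0.9847),
    "disulfide": (-2.01565, -2.0159),
    "oxidation": (+15.99491, +15.9994),
    "dehydration": (-18.01056, -18.0153),
    "deamidation": (+0.98402, +0.9847),
    "co_loss": (-27.99491, -28.0101),
    "carbamidomethyl": (+57.02146, +57.0513),
}


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Residue masses for the 20 standard amino acids plus terminal water."""

    monoisotopic: dict[str, float]
    average: dict[str, float]
    water_monoisotopic: float
    water_average: float

    def __post_init__(self) -> None:
        for aa in STANDARD_AA:
            mono, avg = self.monoisotopic[aa], self.average[aa]
            if not (0 < mono < avg):
                raise ValueError(f"invalid residue masses for {aa}: {mono}, {avg}")

    @classmethod
    def default(cls) -> "AminoAcidMassTable":
        mono = {aa: _pmass.calculate_mass(parsed_sequence=[aa]) for aa in STANDARD_AA}
        avg = {
            aa: _pmass.calculate_mass(parsed_sequence=[aa], average=True)
            for aa in STANDARD_AA
        }
        return cls(
            monoisotopic=mono,
            average=avg,
            water_monoisotopic=_pmass.calculate_mass(formula="H2O"),
            water_average=_pmass.calculate_mass(formula="H2O", average=True),
        )


_DEFAULT_TABLE: Optional[AminoAcidMassTable] = None


def default_mass_table() -> AminoAcidMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AminoAcidMassTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class PeptideMassResult:
    monoisotopic_mass: float
    average_mass: float
    #: (name, mono delta, average delta) for every applied correction
    applied_modifications: tuple[tuple[str, float, float], ...] = ()

    def mass(self, kind: str) -> float:
        if kind == "mono":
            return self.monoisotopic_mass
        if kind == "average":
            return self.average_mass
        raise ValueError(f"unknown mass kind: {kind!r}")


def validate_sequence(sequence: str) -> str:
    """Reject anything outside the 20-letter alphabet, naming the position.

    Ambiguity codes (B/Z/X) and the rare letters U/O are rejected outright:
    a theoretical mass averaged over an ambiguous residue is not a mass.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_AA:
            raise ValueError(
                f"unknown residue {aa!r} at position {i} (0-based); "
                f"only the 20 standard letters are accepted"
            )
    return sequence


def peptide_mass(
    sequence: str,
    *,
    amidated: bool = False,
    disulfide_bonds: int = 0,
    table: Optional[AminoAcidMassTable] = None,
) -> PeptideMassResult:
    """Theoretical mass of a peptide on both scales.

    mass = sum(residues) + water + corrections.  With no flags this equals
    ProtParam's value for the plain sequence.  ``amidated`` converts the
    C-terminal acid to an amide; each disulfide bond removes two hydrogens.
    """
    validate_sequence(sequence)
    if disulfide_bonds < 0:
        raise ValueError("disulfide_bonds must be non-negative")
    if disulfide_bonds > sequence.count("C") // 2:
        raise ValueError(
            f"{disulfide_bonds} disulfide bonds need {2 * disulfide_bonds} "
            f"cysteines; sequence has {sequence.count('C')}"
        )
    table = table or default_mass_table()
    mono = sum(table.monoisotopic[aa] for aa in sequence) + table.water_monoisotopic
    avg = sum(table.average[aa] for aa in sequence) + table.water_average
    mods: list[tuple[str, float, float]] = []
    if amidated:
        dm, da = MOD_DELTAS["amidation"]
        mods.append(("amidation", dm, da))
        mono += dm
        avg += da
    if disulfide_bonds:
        dm, da = MOD_DELTAS["disulfide"]
        mods.append(("disulfide", dm * disulfide_bonds, da * disulfide_bonds))
        mono += dm * disulfide_bonds
        avg += da * disulfide_bonds
    return PeptideMassResult(mono, avg, tuple(mods))


# ---------------------------------------------------------------------------
# precursor model
# ---------------------------------------------------------------------------

Range = tuple[int, int]  # 0-based half-open


@dataclass
class PrecursorModel:
    """A venom precursor dissected into signal / propeptide / mature /
    C-terminal propeptide segments (0-based half-open intervals; any segment
    may be absent).  Segment boundaries come from upstream predictors
    (SignalP/ProP-style output); this class only keeps the bookkeeping
    honest."""

    transcript_id: str
    full_sequence: str
    signal_range: Optional[Range] = None
    propeptide_range: Optional[Range] = None
    mature_range: Optional[Range] = None
    cterm_propeptide_range: Optional[Range] = None
    amidated: bool = False
    disulfide_bond_count: int = 0
    cds_completeness: str = "complete"

    def __post_init__(self) -> None:
        validate_sequence(self.full_sequence)
        if self.cds_completeness not in ("complete", "partial"):
            raise ValueError("cds_completeness must be 'complete' or 'partial'")
        n = len(self.full_sequence)
        ordered = [
            ("signal", self.signal_range),
            ("propeptide", self.propeptide_range),
            ("mature", self.mature_range),
            ("cterm_propeptide", self.cterm_propeptide_range),
        ]
        prev_end = 0
        for name, rng in ordered:
            if rng is None:
                continue
            start, end = rng
            if not (0 <= start < end <= n):
                raise ValueError(f"{name} range {rng} out of bounds for length {n}")
            if start < prev_end:
                raise ValueError(
                    f"{name} range {rng} overlaps or precedes an earlier segment"
                )
            prev_end = end
        if self.cds_completeness == "complete" and (
            self.mature_range is None or self.mature_range[0] >= self.mature_range[1]
        ):
            raise ValueError("complete CDS requires a non-empty mature range")
        if self.mature_range is not None:
            mature = self.segment("mature")
            if self.disulfide_bond_count > mature.count("C") // 2:
                raise ValueError(
                    "disulfide_bond_count exceeds floor(#Cys in mature / 2)"
                )
        elif self.disulfide_bond_count < 0:
            raise ValueError("disulfide_bond_count must be non-negative")

    def segment(self, name: str) -> str:
        rng = getattr(self, f"{name}_range")
        if rng is None:
            return ""
        return self.full_sequence[rng[0] : rng[1]]

    @property
    def mature_sequence(self) -> str:
        return self.segment("mature")


@dataclass(frozen=True)
class AmidationCall:
    mature_sequence: str
    amidated: bool
    #: which convention was applied: "donor-in-propeptide" (the glycine sits
    #: at the start of the C-terminal propeptide; mature reported unchanged)
    #: or "donor-in-mature" (the caller's mature range included the glycine;
    #: it is stripped from the reported mature sequence), or "none".
    convention: str = "none"


_AMIDATION_SIGNAL = re.compile(r"^G[KR]{0,2}")


def detect_amidation(precursor: PrecursorModel) -> AmidationCall:
    """Call C-terminal alpha-amidation from the canonical Gly(+basic) signal.

    The amide donor is a glycine immediately following the mature peptide,
    optionally trailed by one or two basic residues (G, GK, GR, GKR, GRR...)
    at the start of the C-terminal propeptide.  Without a C-terminal
    propeptide the call is always negative -- never an error.
    """
    if precursor.mature_range is None:
        raise ValueError("precursor has no mature range")
    mature = precursor.mature_sequence
    cterm = precursor.segment("cterm_propeptide")
    if not cterm:
        return AmidationCall(mature, False)
    if _AMIDATION_SIGNAL.match(cterm):
        return AmidationCall(mature, True, "donor-in-propeptide")
    # boundary drawn one residue late: glycine kept inside the mature range,
    # with the basic remainder of the signal opening the propeptide
    if mature.endswith("G") and cterm[0] in "KR":
        return AmidationCall(mature[:-1], True, "donor-in-mature")
    return AmidationCall(mature, False)


_GAP_CHARS = set("-.")


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two pre-aligned, equal-length sequences.

    Gap characters ('-' or '.') are allowed and always count as mismatches.
    The reported value truncates at one decimal (56/58 = 96.5517 -> 96.5),
    the convention venomics reports follow for mature-level identities; the
    full-precision ratio is trivially ``matches / length`` if needed.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences must be pre-aligned to equal length "
            f"({len(seq_a)} vs {len(seq_b)}); alignment is upstream"
        )
    if not seq_a:
        raise ValueError("empty alignment")
    matches = sum(
        1
        for x, y in zip(seq_a, seq_b)
        if x == y and x not in _GAP_CHARS
    )
    return float(
        Decimal(100 * matches) / Decimal(len(seq_a)) // Decimal("0.1") * Decimal("0.1")
    )
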