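"""In-silico tryptic digestion, PSM acceptance and sequence coverage.

Trypsin cleaves after Lys/Arg except when the next residue is Pro (the
classic specificity; the proline rule can be switched off).  Peptides are
all contiguous unions of 1..(max_missed+1) fully-cleaved fragments, so at
zero missed cleavages they partition the parent.

Peptide-spectrum matches (PSMs) from an upstream search engine are
accepted when the identification score is strictly greater than the score
cut-off and at least the minimum number of fragment ions was observed
(defaults 25 and 2).  Coverage of a parent protein is the union of all
exact-occurrence intervals of its accepted peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Optional, Sequence, Union

from . import chem

__all__ = [
    "DigestPeptide",
    "PSMRecord",
    "CoverageReport",
    "cleavage_sites",
    "tryptic_digest",
    "digest_peptide_masses",
    "psm_filter",
    "compute_coverage",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DigestPeptide:
    parent_id: str
    start: int  # 0-based half-open interval in the parent
    end: int
    sequence: str
    missed_cleavages: int
    modifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")


@dataclass(frozen=True)
class PSMRecord:
    sequence: str
    parent_id: str
    score: float
    fragment_count: int
    modifications: tuple[str, ...] = ()
    fdr_stratum: Optional[str] = None  # e.g. "strict" (0.01) / "relaxed" (0.05)

    def __post_init__(self) -> None:
        if self.score != self.score or self.score in (float("inf"), float("-inf")):
            raise ValueError("score must be finite")
        if self.fragment_count < 0:
            raise ValueError("fragment_count must be non-negative")


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Internal cut positions: a site ``i`` means a cut between residues
    ``i`` and ``i+1`` (after a K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR"
        and not (proline_rule and sequence[i + 1] == "P")
    ]


def tryptic_digest(
    parent: Union[str, tuple[str, str]],
    max_missed: int = 2,
    min_length: int = 1,
    proline_rule: bool = True,
) -> list[DigestPeptide]:
    """All tryptic peptides of ``parent`` with up to ``max_missed`` missed
    cleavages, ordered by (start, end).

    ``parent`` is either a plain sequence or an (id, sequence) pair.
    """
    parent_id, sequence = parent if isinstance(parent, tuple) else ("", parent)
    if not sequence:
        raise ValueError("empty parent sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    sites = cleavage_sites(sequence, proline_rule)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides: list[DigestPeptide] = []
    for a in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            b = a + missed + 1
            if b >= len(bounds):
                break
            start, end = bounds[a], bounds[b]
            if end - start < min_length:
                continue
            peptides.append(
                DigestPeptide(
                    parent_id=parent_id,
                    start=start,
                    end=end,
                    sequence=sequence[start:end],
                    missed_cleavages=missed,
                )
            )
    return peptides


def digest_peptide_masses(
    peptide: DigestPeptide,
    carbamidomethyl: bool = True,
    variable_mods: bool = True,
    max_variable: int = 3,
) -> list[tuple[str, float]]:
    """Monoisotopic mass variants of a digest peptide.

    Carbamidomethyl-Cys is a fixed modification (alkylation is part of the
    sample preparation); methionine oxidation and C-terminal amidation are
    enumerated as variable variants, capped at ``max_variable`` variable
    sites per peptide.  Returns (description, mass) pairs, base form first.
    """
    base = chem.peptide_mass(peptide.sequence).monoisotopic_mass
    if carbamidomethyl:
        base += peptide.sequence.count("C") * chem.MOD_DELTAS["carbamidomethyl"][0]
    variants: list[tuple[str, float]] = [("base", base)]
    if not variable_mods:
        return variants
    ox = chem.MOD_DELTAS["oxidation"][0]
    amid = chem.MOD_DELTAS["amidation"][0]
    met_positions = [i for i, aa in enumerate(peptide.sequence) if aa == "M"]
    for n_ox in range(1, min(len(met_positions), max_variable) + 1):
        variants.append((f"{n_ox}x oxidation", base + n_ox * ox))
    amidated: list[tuple[str, float]] = []
    for name, mass in variants:
        n_sites = 1 + (0 if name == "base" else int(name.split("x")[0]))
        if n_sites <= max_variable:
            label = "amidation" if name == "base" else f"{name} + amidation"
            amidated.append((label, mass + amid))
    return variants + amidated


def psm_filter(
    records: Iterable[PSMRecord],
    score_min: float = 25.0,
    fragments_min: int = 2,
    fdr_strata: Optional[Sequence[str]] = None,
) -> list[PSMRecord]:
    """Positive hits: score strictly above ``score_min`` AND at least
    ``fragments_min`` fragment ions; optionally restricted to the given
    FDR strata labels (the stratum is an engine-side label, not estimated
    here)."""
    accepted = [
        r
        for r in records
        if r.score > score_min
        and r.fragment_count >= fragments_min
        and (fdr_strata is None or r.fdr_stratum in fdr_strata)
    ]
    return accepted


@dataclass(frozen=True)
class CoverageReport:
    parent_id: str
    covered_positions: frozenset[int]
    coverage_percent: float  # one decimal, half-up


def _percent(covered: int, total: int) -> float:
    return float(
        (Decimal(100 * covered) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def compute_coverage(
    parent: tuple[str, str],
    peptides: Iterable[Union[DigestPeptide, PSMRecord, str]],
) -> CoverageReport:
    """Project accepted peptides onto the parent and report % residues hit.

    Peptides are located by exact substring match and every occurrence
    counts; a peptide absent from the parent contributes nothing but is
    logged (engine I/L swaps and de novo tails end up there).
    """
    parent_id, sequence = parent
    if not sequence:
        raise ValueError("empty parent sequence")
    covered: set[int] = set()
    for pep in peptides:
        pep_seq = pep if isinstance(pep, str) else pep.sequence
        found = False
        pos = sequence.find(pep_seq)
        while pos != -1:
            covered.update(range(pos, pos + len(pep_seq)))
            found = True
            pos = sequence.find(pep_seq, pos + 1)
        if not found:
            log.info(
                "coverage: peptide %r not found in parent %s", pep_seq, parent_id
            )
    return CoverageReport(
        parent_id=parent_id,
        covered_positions=frozenset(covered),
        coverage_percent=_percent(len(covered), len(sequence)),
    )
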