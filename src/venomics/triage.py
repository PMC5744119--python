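"""Venom-transcript triage, family classification and systematic naming.

A transcript is a venom-component candidate when its annotation evidence
satisfies any of three criteria: (1) similarity to a previously reported
EST from the same species, (2) one of the distinctive venom-associated
protein domains, or (3) similarity to an entry of a curated animal-toxin
database -- each at a configurable e-value cut-off (default 1e-4).

Candidates are classified by an ordered keyword rulebook into a
family/subtype taxonomy (NaT, KTx, CaT, HDP, Enz, PIn, Oth) and named
systematically: three letters of species, three of family, three of
subtype, and a two-digit serial, e.g. ``TatNaTAlp01``.  Transcripts whose
encoded sequence exactly matches a previously published one keep the
published name.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "AnnotationEvidence",
    "TriageConfig",
    "TriageResult",
    "VenomClassification",
    "FamilyTally",
    "ClassificationRule",
    "FAMILY_SUBTYPES",
    "DEFAULT_VENOM_DOMAINS",
    "triage_transcript",
    "classify_family",
    "assign_names",
    "tally_families",
    "default_rulebook",
    "load_rulebook",
]

Hit = tuple[str, float, float]  # (subject id, identity %, e-value)
DomainHit = tuple[str, str, float]  # (accession, domain name, e-value)


@dataclass
class AnnotationEvidence:
    """Upstream annotation evidence for one transcript (BLAST/Pfam-style
    output consumed as tables; no searching happens here)."""

    transcript_id: str
    est_hits: list[Hit] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    toxin_db_hits: list[Hit] = field(default_factory=list)
    keyword_descriptor: str = ""

    def __post_init__(self) -> None:
        for sid, ident, ev in self.est_hits + self.toxin_db_hits:
            if ev < 0 or not (0 <= ident <= 100):
                raise ValueError(f"bad hit ({sid}, {ident}, {ev})")
        for acc, name, ev in self.domain_hits:
            if ev < 0:
                raise ValueError(f"bad domain hit ({acc}, {name}, {ev})")


#: Venom-associated domain vocabulary used by triage criterion 2.  The
#: curated list of distinctive venom domains is not fully enumerable from
#: public sources, so this default is an editable config: any domain hit
#: whose name contains one of these tokens (case-insensitive) counts.
DEFAULT_VENOM_DOMAINS: tuple[str, ...] = (
    "defensin",
    "phospholipase",
    "cap",
    "scp",
    "kunitz",
    "serpin",
    "wap",
    "svwc",
    "la1",
    "toxin",
    "hyaluronidase",
    "peptidase",
    "metalloprote",
    "ick",
    "ddh",
)


@dataclass
class TriageConfig:
    evalue_max: float = 1e-4
    identity_min: float = 0.0
    venom_domains: tuple[str, ...] = DEFAULT_VENOM_DOMAINS


@dataclass(frozen=True)
class TriageResult:
    transcript_id: str
    is_candidate: bool
    satisfied_criteria: frozenset[int]


def triage_transcript(
    evidence: AnnotationEvidence, config: Optional[TriageConfig] = None
) -> TriageResult:
    """Flag a transcript as a venom-component candidate (criterion 1 OR 2
    OR 3); the satisfied criteria are enumerated for provenance."""
    cfg = config or TriageConfig()
    satisfied: set[int] = set()
    if any(
        ev <= cfg.evalue_max and ident >= cfg.identity_min
        for _, ident, ev in evidence.est_hits
    ):
        satisfied.add(1)
    vocab = tuple(tok.lower() for tok in cfg.venom_domains)
    if any(
        ev <= cfg.evalue_max and any(tok in name.lower() for tok in vocab)
        for _, name, ev in evidence.domain_hits
    ):
        satisfied.add(2)
    if any(
        ev <= cfg.evalue_max and ident >= cfg.identity_min
        for _, ident, ev in evidence.toxin_db_hits
    ):
        satisfied.add(3)
    return TriageResult(evidence.transcript_id, bool(satisfied), frozenset(satisfied))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

#: subtype vocabulary per family
FAMILY_SUBTYPES: dict[str, tuple[str, ...]] = {
    "NaT": ("Alp", "Bet"),
    "KTx": ("Alp", "Bet", "Kap", "Del", "Scr"),
    "CaT": ("Clc", "Lio", "Ome"),
    "HDP": ("Def", "ND1", "ND2", "ND3", "ND4", "ND5", "Ani", "Wap"),
    "Enz": ("PA2", "PLB", "PLD", "SeP", "MtP", "Hya"),
    "PIn": ("Srp", "Kun"),
    "Oth": ("La1", "CRI", "Und"),
}

#: the disulfide-bound-peptide umbrella used in composition roll-ups
DBP_FAMILIES = ("NaT", "KTx", "CaT")


@dataclass(frozen=True)
class VenomClassification:
    species_code: str
    family_code: str
    subtype_code: str
    index: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.species_code) != 3 or not self.species_code[0].isupper():
            raise ValueError(f"species code must be 3 letters, capitalised: "
                             f"{self.species_code!r}")
        if self.family_code not in FAMILY_SUBTYPES:
            raise ValueError(f"unknown family code {self.family_code!r}")
        if self.subtype_code not in FAMILY_SUBTYPES[self.family_code]:
            raise ValueError(
                f"subtype {self.subtype_code!r} invalid for family "
                f"{self.family_code!r}"
            )
        if self.index is not None and self.index < 1:
            raise ValueError("index starts at 01")

    @property
    def systematic_name(self) -> str:
        if self.index is None:
            raise ValueError("no index assigned yet")
        return f"{self.species_code}{self.family_code}{self.subtype_code}" \
               f"{self.index:02d}"


@dataclass(frozen=True)
class ClassificationRule:
    keywords: tuple[str, ...]  # all must occur (case-insensitive substring)
    family: str
    subtype: str


def default_rulebook() -> list[ClassificationRule]:
    with resources.files("venomics.data").joinpath("rulebook.yaml").open() as fh:
        return load_rulebook(fh)


def load_rulebook(stream) -> list[ClassificationRule]:
    doc = yaml.safe_load(stream)
    rules = []
    for entry in doc["rules"]:
        rule = ClassificationRule(
            tuple(k.lower() for k in entry["keywords"]),
            entry["family"],
            entry["subtype"],
        )
        if rule.family not in FAMILY_SUBTYPES:
            raise ValueError(f"unknown family in rulebook: {rule.family!r}")
        if rule.subtype not in FAMILY_SUBTYPES[rule.family]:
            raise ValueError(
                f"subtype {rule.subtype!r} invalid for family {rule.family!r}"
            )
        rules.append(rule)
    return rules


def classify_family(
    evidence: AnnotationEvidence,
    rulebook: Optional[Sequence[ClassificationRule]] = None,
    species_code: str = "Tat",
) -> VenomClassification:
    """First matching rule in the ordered rulebook wins; unmatched
    candidates fall back to (Oth, Und)."""
    rules = default_rulebook() if rulebook is None else rulebook
    haystack = " ".join(
        [evidence.keyword_descriptor] + [name for _, name, _ in evidence.domain_hits]
    ).lower()
    for rule in rules:
        if all(kw in haystack for kw in rule.keywords):
            return VenomClassification(species_code, rule.family, rule.subtype)
    return VenomClassification(species_code, "Oth", "Und")


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


def assign_names(
    classified: Mapping[str, VenomClassification],
    sequences: Mapping[str, str],
    registry: Optional[Mapping[str, str]] = None,
    *,
    index_width: int = 2,
) -> dict[str, str]:
    """Assign systematic (or registry-honoured) names to transcripts.

    ``registry`` maps exact sequences to previously published names; a
    registered sequence never receives a new systematic name.  Remaining
    transcripts in each (species, family, subtype) group are numbered 01,
    02, ... in ascending transcript_id order (lexicographic: reproducible
    without expression data).
    """
    registry = registry or {}
    names: dict[str, str] = {}
    groups: dict[tuple[str, str, str], list[str]] = {}
    for tid in sorted(classified):
        cls = classified[tid]
        seq = sequences.get(tid, "")
        if seq in registry:
            names[tid] = registry[seq]
            continue
        groups.setdefault(
            (cls.species_code, cls.family_code, cls.subtype_code), []
        ).append(tid)
    limit = 10**index_width - 1
    for key, tids in groups.items():
        if len(tids) > limit:
            raise ValueError(
                f"{len(tids)} transcripts in subtype {key}: the "
                f"{index_width}-digit serial is exhausted; widen index_width "
                f"explicitly"
            )
        for nn, tid in enumerate(sorted(tids), start=1):
            names[tid] = f"{key[0]}{key[1]}{key[2]}{nn:0{index_width}d}"
    if len(set(names.values())) != len(names):
        dupes = [n for n, c in Counter(names.values()).items() if c > 1]
        raise ValueError(f"duplicate names produced: {dupes}")
    return names


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyTally:
    by_family: dict[str, int]
    by_subtype: dict[tuple[str, str], int]
    #: composition roll-up with NaT+KTx+CaT merged under "DBP" and the Oth
    #: subtypes (La1, CRI, Und) reported individually
    rollup: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.by_family.values())


def tally_families(classified: Iterable[VenomClassification]) -> FamilyTally:
    by_family: Counter = Counter()
    by_subtype: Counter = Counter()
    for cls in classified:
        by_family[cls.family_code] += 1
        by_subtype[(cls.family_code, cls.subtype_code)] += 1
    rollup = {
        "DBP": sum(by_family[f] for f in DBP_FAMILIES),
        "HDP": by_family["HDP"],
        "Enz": by_family["Enz"],
        "La1": by_subtype[("Oth", "La1")],
        "PIn": by_family["PIn"],
        "CRI": by_subtype[("Oth", "CRI")],
        "Und": by_subtype[("Oth", "Und")],
    }
    return FamilyTally(dict(by_family), dict(by_subtype), rollup)
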