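"""Deterministic synthetic fixtures with stage-wise ground truth.

Each generator is a pure function of (spec, seed): the same inputs give
byte-identical outputs, and every fixture ships the ground truth the
corresponding pipeline stage must recover, so tests assert exact recovery
rather than plausibility.

The default transcript fixture reproduces the family composition of an
annotated scorpion venom-gland transcriptome: 41 disulfide-bound
peptides (Na/K/Ca-channel toxins), 17 host-defense peptides, 55 enzymes,
7 La1-like peptides, 24 protease inhibitors, 8 CRISPs and 8 undefined
venom components -- 160 candidates -- plus housekeeping decoys that must
fail triage.  Residue composition is biased per class (cysteine-rich for
DBPs, cationic/hydrophobic for short antimicrobials) for cosmetic
realism; no correctness claim rests on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .chem import PrecursorModel
from .fingerprint import (
    DEFAULT_DELTA_RULES,
    DEFAULT_TOLERANCE,
    DeltaRule,
    Fingerprint,
    MassPeak,
    mass_kind_for,
)
from .digest import PSMRecord, _percent, tryptic_digest
from .triage import AnnotationEvidence

__all__ = [
    "DEFAULT_FAMILY_COMPOSITION",
    "FixtureSpec",
    "TranscriptFixture",
    "FingerprintFixture",
    "PSMFixture",
    "make_transcript_fixture",
    "make_fingerprint_fixture",
    "make_psm_fixture",
]

#: the venom-candidate composition the default fixture reproduces exactly
DEFAULT_FAMILY_COMPOSITION: dict[str, int] = {
    "DBP": 41,
    "HDP": 17,
    "Enz": 55,
    "La1": 7,
    "PIn": 24,
    "CRI": 8,
    "Und": 8,
}

#: canonical subtype weights within each roll-up group; counts other than
#: the default are apportioned by largest remainder over these weights
_SUBTYPE_WEIGHTS: dict[str, list[tuple[str, str, int]]] = {
    "DBP": [
        ("NaT", "Alp", 3),
        ("NaT", "Bet", 10),
        ("KTx", "Alp", 15),
        ("KTx", "Kap", 1),
        ("KTx", "Del", 2),
        ("KTx", "Scr", 3),
        ("CaT", "Clc", 2),
        ("CaT", "Lio", 4),
        ("CaT", "Ome", 1),
    ],
    "HDP": [
        ("HDP", "Def", 4),
        ("HDP", "ND2", 2),
        ("HDP", "ND3", 2),
        ("HDP", "ND4", 7),
        ("HDP", "Ani", 1),
        ("HDP", "Wap", 1),
    ],
    "Enz": [
        ("Enz", "PA2", 20),
        ("Enz", "PLB", 1),
        ("Enz", "SeP", 18),
        ("Enz", "MtP", 14),
        ("Enz", "Hya", 2),
    ],
    "PIn": [("PIn", "Srp", 19), ("PIn", "Kun", 5)],
    "La1": [("Oth", "La1", 1)],
    "CRI": [("Oth", "CRI", 1)],
    "Und": [("Oth", "Und", 1)],
}

#: annotation text per subtype; the default rulebook maps each back to its
#: intended class (first-match precedence was checked against every entry)
_DESCRIPTORS: dict[tuple[str, str], str] = {
    ("NaT", "Alp"): "alpha-toxin sodium channel toxin precursor",
    ("NaT", "Bet"): "beta-toxin sodium channel toxin precursor",
    ("KTx", "Alp"): "alpha-toxin potassium channel blocker",
    ("KTx", "Bet"): "beta-toxin potassium channel blocker",
    ("KTx", "Kap"): "kappa-toxin potassium channel blocker",
    ("KTx", "Del"): "delta-toxin potassium channel kunitz-type blocker",
    ("KTx", "Scr"): "scorpine-like two-domain antimicrobial toxin",
    ("CaT", "Clc"): "calcin ryanodine receptor toxin",
    ("CaT", "Lio"): "liotoxin-like calcium channel toxin",
    ("CaT", "Ome"): "omegascorpin omega-agatoxin-like calcium channel toxin",
    ("HDP", "Def"): "beta-defensin antimicrobial peptide",
    ("HDP", "ND2"): "ndbp-2 family long-chain antimicrobial peptide",
    ("HDP", "ND3"): "ndbp-3 family antimicrobial peptide",
    ("HDP", "ND4"): "ndbp-4 family short antimicrobial peptide",
    ("HDP", "Ani"): "anionic host defense peptide",
    ("HDP", "Wap"): "waprin-like peptide",
    ("Enz", "PA2"): "phospholipase a2",
    ("Enz", "PLB"): "phospholipase b",
    ("Enz", "SeP"): "venom serine protease",
    ("Enz", "MtP"): "venom metalloprotease",
    ("Enz", "Hya"): "hyaluronidase",
    ("PIn", "Srp"): "serpin serine protease inhibitor",
    ("PIn", "Kun"): "kunitz-type protease inhibitor",
    ("Oth", "La1"): "la1-like svwc venom peptide",
    ("Oth", "CRI"): "cysteine-rich secretory protein crisp",
    ("Oth", "Und"): "unknown venom protein of undefined function",
}

_DECOY_DESCRIPTORS = (
    "60s ribosomal protein",
    "actin cytoskeletal protein",
    "elongation factor 1-alpha",
    "heat shock cognate protein",
    "atp synthase subunit",
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    family_composition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_COMPOSITION)
    )
    decoy_count: int = 40
    registry_duplicates: int = 2
    artifact_plant_rate: float = 0.5
    psm_score_distribution: tuple[float, float] = (25.0, 15.0)
    peptide_length_range: tuple[int, int] = (13, 60)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.family_composition.values()):
            raise ValueError("composition counts must be non-negative")
        if not 0 <= self.artifact_plant_rate <= 1:
            raise ValueError("artifact_plant_rate must be in [0, 1]")
        if self.decoy_count < 0 or self.registry_duplicates < 0:
            raise ValueError("counts must be non-negative")


def _apportion(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over integer weights."""
    wsum = sum(weights)
    if wsum == 0 or total == 0:
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(weights)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


def subtype_allocation(
    composition: Optional[dict[str, int]] = None,
) -> list[tuple[str, str, int]]:
    """Expand a roll-up composition into (family, subtype, count) triples."""
    composition = (
        dict(DEFAULT_FAMILY_COMPOSITION) if composition is None else composition
    )
    allocation = []
    for group, count in composition.items():
        if group not in _SUBTYPE_WEIGHTS:
            raise ValueError(f"unknown composition group {group!r}")
        entries = _SUBTYPE_WEIGHTS[group]
        for (family, subtype, _), n in zip(
            entries, _apportion(count, [w for _, _, w in entries])
        ):
            if n:
                allocation.append((family, subtype, n))
    return allocation


# residue pools for cosmetic class realism
_GENERIC = list("ACDEFGHIKLMNPQRSTVWY")
_HYDROPHOBIC = list("AFILMVWG")
_CATIONIC = list("KRLIFGAW")


def _draw(rng: np.random.Generator, pool: Sequence[str], n: int) -> str:
    return "".join(rng.choice(pool, size=n))


def _mature_sequence(
    rng: np.random.Generator, family: str, subtype: str, spec: FixtureSpec
) -> tuple[str, int]:
    """Return (mature sequence, disulfide bond count) for one class."""
    lo, hi = spec.peptide_length_range
    if family in ("NaT", "KTx", "CaT") or subtype in ("Def", "Wap", "Kun", "CRI"):
        length = int(rng.integers(max(lo, 28), max(hi, 40)))
        bonds = int(rng.integers(2, 5))
        seq = list(_draw(rng, _GENERIC, length))
        positions = rng.choice(length, size=2 * bonds, replace=False)
        for p in positions:
            seq[p] = "C"
        return "".join(seq), bonds
    if subtype in ("ND2", "ND3", "ND4", "Ani"):
        length = 13 if subtype == "ND4" else int(rng.integers(19, 48))
        seq = _draw(rng, _CATIONIC, length).replace("C", "A")
        return seq, 0
    # enzymes, serpins, La1, undefined: mid-size generic chains
    length = int(rng.integers(max(lo, 40), max(hi, 90)))
    return _draw(rng, _GENERIC, length), 0


def _evidence_for(
    rng: np.random.Generator, tid: str, family: str, subtype: str
) -> AnnotationEvidence:
    evalue = float(10.0 ** rng.uniform(-30, -6))
    identity = float(rng.uniform(45, 98))
    evidence = AnnotationEvidence(
        transcript_id=tid,
        toxin_db_hits=[(f"TOXDB_{tid}", identity, evalue)],
        keyword_descriptor=_DESCRIPTORS[(family, subtype)],
    )
    if rng.random() < 0.5:
        evidence.domain_hits.append(
            (f"PF{int(rng.integers(10000, 99999)):05d}", "toxin-like domain",
             float(10.0 ** rng.uniform(-20, -5)))
        )
    if rng.random() < 0.3:
        evidence.est_hits.append(
            (f"EST_{tid}", float(rng.uniform(80, 100)),
             float(10.0 ** rng.uniform(-40, -10)))
        )
    return evidence


@dataclass(frozen=True)
class TranscriptFixture:
    seed: int
    precursors: tuple[PrecursorModel, ...]
    evidence: tuple[AnnotationEvidence, ...]
    registry: dict[str, str]  # mature sequence -> published name
    expected_rollup: dict[str, int]
    expected_candidates: int


def make_transcript_fixture(spec: Optional[FixtureSpec] = None) -> TranscriptFixture:
    """Generate precursors + evidence engineered so that triage and
    classification recover ``spec.family_composition`` exactly, plus
    decoys that must fail triage and registry duplicates that must keep
    their published names."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    allocation = subtype_allocation(spec.family_composition)
    precursors: list[PrecursorModel] = []
    evidence: list[AnnotationEvidence] = []
    serial = 0
    registry_candidates: list[str] = []  # mature sequences eligible to register
    for family, subtype, count in allocation:
        for _ in range(count):
            serial += 1
            tid = f"comp{serial:05d}_c0_seq1"
            signal = "M" + _draw(rng, _HYDROPHOBIC, 21)
            mature, bonds = _mature_sequence(rng, family, subtype, spec)
            cterm = ""
            amidated = False
            if subtype == "ND4":
                cterm = "GKR" + _draw(rng, _GENERIC, 4).replace("G", "A")
                amidated = True
            full = signal + mature + cterm
            precursors.append(
                PrecursorModel(
                    transcript_id=tid,
                    full_sequence=full,
                    signal_range=(0, len(signal)),
                    mature_range=(len(signal), len(signal) + len(mature)),
                    cterm_propeptide_range=(
                        (len(signal) + len(mature), len(full)) if cterm else None
                    ),
                    amidated=amidated,
                    disulfide_bond_count=bonds,
                    cds_completeness="complete",
                )
            )
            evidence.append(_evidence_for(rng, tid, family, subtype))
            if subtype in ("ND4", "La1"):
                registry_candidates.append(mature)
    registry = {
        seq: name
        for seq, name in zip(registry_candidates, ("ViCT2", "ViLa1lp1", "ViScplp2"))
    }
    registry = dict(list(registry.items())[: spec.registry_duplicates])
    for _ in range(spec.decoy_count):
        serial += 1
        tid = f"comp{serial:05d}_c0_seq1"
        seq = "M" + _draw(rng, _GENERIC, int(rng.integers(60, 200)))
        precursors.append(
            PrecursorModel(
                transcript_id=tid,
                full_sequence=seq,
                mature_range=(1, len(seq)),
                cds_completeness="complete",
            )
        )
        descriptor = str(rng.choice(_DECOY_DESCRIPTORS))
        ev = AnnotationEvidence(transcript_id=tid, keyword_descriptor=descriptor)
        if rng.random() < 0.5:  # a hit too weak to pass the e-value cut-off
            ev.toxin_db_hits.append(
                (f"TOXDB_{tid}", float(rng.uniform(20, 40)),
                 float(10.0 ** rng.uniform(-3, 1)))
            )
        evidence.append(ev)
    return TranscriptFixture(
        seed=spec.seed,
        precursors=tuple(precursors),
        evidence=tuple(evidence),
        registry=registry,
        expected_rollup=dict(spec.family_composition),
        expected_candidates=sum(spec.family_composition.values()),
    )


# ---------------------------------------------------------------------------
# fingerprint fixture
# ---------------------------------------------------------------------------

_RT_BINS = tuple((20.0 * k, 20.0 * (k + 1)) for k in range(9))


@dataclass(frozen=True)
class FingerprintFixture:
    seed: int
    fingerprint: Fingerprint  # bases + planted satellites
    base_peaks: tuple[MassPeak, ...]
    #: (parent peak, satellite peak, rule name) for every planted artifact
    planted: tuple[tuple[MassPeak, MassPeak, str], ...]


def default_base_masses(rng: np.random.Generator, n: int = 30) -> list[float]:
    """Base masses spaced >= 120 Da apart: more than twice the largest
    delta rule plus tolerance, so no pair that crosses bases (base-base,
    base-satellite or satellite-satellite) can ever match a rule."""
    masses: list[float] = []
    while len(masses) < n:
        m = float(np.round(rng.uniform(1000, 16000), 2))
        if all(abs(m - other) >= 120 for other in masses):
            masses.append(m)
    return sorted(masses)


def make_fingerprint_fixture(
    spec: Optional[FixtureSpec] = None,
    base_masses: Optional[Sequence[float]] = None,
    rules: Sequence[DeltaRule] = DEFAULT_DELTA_RULES,
    jitter_beyond_tolerance: bool = False,
) -> FingerprintFixture:
    """Plant one delta-rule satellite (co-eluting with its parent) on a
    ``artifact_plant_rate`` fraction of base peaks.

    Jitter stays below half the pairing tolerance, so curation must
    remove every satellite and no base; with ``jitter_beyond_tolerance``
    the satellites are displaced past the tolerance and must all survive
    (negative control).  The negative control plants only the first rule
    in ``rules`` -- with the defaults that is the sodium adduct, whose
    delta sits far from every other rule, so a displaced satellite cannot
    alias a different rule either."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream per stage
    if base_masses is None:
        base_masses = default_base_masses(rng)
    if any(m <= 0 for m in base_masses):
        raise ValueError("base masses must be positive")
    base_peaks: list[MassPeak] = []
    planted: list[tuple[MassPeak, MassPeak, str]] = []
    peaks: list[MassPeak] = []
    for m in base_masses:
        rt_bin = _RT_BINS[int(rng.integers(0, len(_RT_BINS)))]
        base = MassPeak(m, rt_bin)
        base_peaks.append(base)
        peaks.append(base)
        if rng.random() >= spec.artifact_plant_rate:
            continue
        if jitter_beyond_tolerance:
            rule = rules[0]
        else:
            rule = rules[int(rng.integers(0, len(rules)))]
        satellite_mass = m + rule.delta if rule.derived_is == "heavier" else (
            m - abs(rule.delta)
        )
        if satellite_mass <= 0:
            continue
        both_mono = (
            mass_kind_for(m) == "mono" and mass_kind_for(satellite_mass) == "mono"
        )
        tol = DEFAULT_TOLERANCE["mono" if both_mono else "average"]
        if jitter_beyond_tolerance:
            jitter = float(rng.uniform(1.5, 3.0)) * tol * (1 if rng.random() < 0.5 else -1)
        else:
            jitter = float(rng.uniform(-0.4, 0.4)) * tol
        satellite = MassPeak(satellite_mass + jitter, rt_bin)
        peaks.append(satellite)
        planted.append((base, satellite, rule.name))
    return FingerprintFixture(
        seed=spec.seed,
        fingerprint=Fingerprint(tuple(peaks), provenance=f"synthetic(seed={spec.seed})"),
        base_peaks=tuple(base_peaks),
        planted=tuple(planted),
    )


# ---------------------------------------------------------------------------
# PSM fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSMFixture:
    seed: int
    records: tuple[PSMRecord, ...]
    #: parent_id -> coverage percent implied by the records that pass the
    #: default acceptance filter, from a direct position-union count
    expected_coverage: dict[str, float]


def make_psm_fixture(
    parents: Sequence[tuple[str, str]],
    spec: Optional[FixtureSpec] = None,
) -> PSMFixture:
    """Sample tryptic peptides from each parent and attach scores and
    fragment counts straddling the acceptance thresholds (score 25,
    2 fragments), including exact boundary cases."""
    if not parents:
        raise ValueError("no parent sequences")
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed + 2)
    loc, spread = spec.psm_score_distribution
    records: list[PSMRecord] = []
    expected: dict[str, float] = {}
    for parent_id, sequence in parents:
        peptides = [
            p for p in tryptic_digest((parent_id, sequence), max_missed=2)
            if len(p.sequence) >= 5
        ]
        covered: set[int] = set()
        if not peptides:
            expected[parent_id] = 0.0
            continue
        k = min(len(peptides), int(rng.integers(3, 9)))
        chosen = rng.choice(len(peptides), size=k, replace=False)
        for idx in chosen:
            pep = peptides[int(idx)]
            fate = rng.random()
            if fate < 0.55:  # accepted
                score = loc + abs(float(rng.normal(0, spread))) + 0.01
                fragments = int(rng.integers(2, 14))
                accepted = True
            elif fate < 0.75:  # low score (includes the exact boundary)
                score = loc if fate < 0.6 else loc - abs(float(rng.normal(0, 5)))
                fragments = int(rng.integers(2, 14))
                accepted = False
            else:  # too few fragments
                score = loc + abs(float(rng.normal(0, spread))) + 0.01
                fragments = int(rng.integers(0, 2))
                accepted = False
            records.append(
                PSMRecord(
                    sequence=pep.sequence,
                    parent_id=parent_id,
                    score=round(score, 2),
                    fragment_count=fragments,
                    fdr_stratum="strict" if rng.random() < 0.8 else "relaxed",
                )
            )
            if accepted:
                # construction-level truth: union of all exact occurrences
                pos = sequence.find(pep.sequence)
                while pos != -1:
                    covered.update(range(pos, pos + len(pep.sequence)))
                    pos = sequence.find(pep.sequence, pos + 1)
        expected[parent_id] = _percent(len(covered), len(sequence))
    return PSMFixture(seed=spec.seed, records=tuple(records), expected_coverage=expected)
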