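"""Format readers/writers and report rendering.

TSV (tab-separated, UTF-8, Unix newlines) is the canonical tabular
dialect; masses are rendered to 2 decimals and percentages to 1, matching
the precisions of published venomics tables.  All outputs are
deterministic functions of their inputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import PrecursorModel
from .digest import CoverageReport, PSMRecord
from .fingerprint import FingerprintSummary
from .matching import MassMatch
from .physchem import PhyschemProfile
from .triage import AnnotationEvidence, Hit, DomainHit

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "read_psm_tsv",
    "read_precursor_table",
    "write_precursor_table",
    "render_match_report",
    "render_coverage_report",
    "render_physchem_report",
    "render_classification_report",
    "render_summary_report",
    "go_tally",
    "config_hash",
]

log = logging.getLogger(__name__)

GO_ROOTS = ("Biological Process", "Cellular Component", "Molecular Function")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """(id, sequence) pairs; lowercase letters are uppercased with a log
    note so downstream validation sees one alphabet."""
    records = []
    # the Pearson dialect tolerates ';' comment lines (we write the seed
    # provenance as one)
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("read_fasta: uppercased sequence %s", rec.id)
            seq = seq.upper()
        records.append((rec.id, seq))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]],
    path: Union[str, Path],
    header_comment: str = "",
) -> None:
    """Write records wrapped at 60 columns; round-trips id + sequence."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f";{header_comment}\n")
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
            fh,
            "fasta",
        )


# ---------------------------------------------------------------------------
# evidence / PSM / precursor tables
# ---------------------------------------------------------------------------


def _format_hits(hits: Sequence[tuple]) -> str:
    return ";".join("|".join(str(x) for x in h) for h in hits)


def _parse_hits(cell: str, three_floats: bool) -> list[tuple]:
    if not cell or pd.isna(cell):
        return []
    out = []
    for chunk in str(cell).split(";"):
        a, b, c = chunk.split("|")
        out.append((a, float(b), float(c)) if three_floats else (a, b, float(c)))
    return out


def write_evidence_tsv(
    evidence: Iterable[AnnotationEvidence], path: Union[str, Path]
) -> None:
    rows = [
        {
            "transcript_id": ev.transcript_id,
            "est_hits": _format_hits(ev.est_hits),
            "domain_hits": _format_hits(ev.domain_hits),
            "toxin_db_hits": _format_hits(ev.toxin_db_hits),
            "keyword_descriptor": ev.keyword_descriptor,
        }
        for ev in evidence
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_evidence_tsv(path: Union[str, Path]) -> list[AnnotationEvidence]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        AnnotationEvidence(
            transcript_id=row["transcript_id"],
            est_hits=_parse_hits(row.get("est_hits", ""), True),
            domain_hits=_parse_hits(row.get("domain_hits", ""), False),
            toxin_db_hits=_parse_hits(row.get("toxin_db_hits", ""), True),
            keyword_descriptor=row.get("keyword_descriptor", ""),
        )
        for _, row in df.iterrows()
    ]


def read_psm_tsv(path: Union[str, Path]) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PSMRecord(
            sequence=row["sequence"],
            parent_id=row["parent_id"],
            score=float(row["score"]),
            fragment_count=int(row["fragment_count"]),
            fdr_stratum=row["fdr_stratum"] if "fdr_stratum" in df.columns else None,
        )
        for _, row in df.iterrows()
    ]


def write_psm_tsv(records: Iterable[PSMRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "parent_id": r.parent_id,
            "score": r.score,
            "fragment_count": r.fragment_count,
            "fdr_stratum": r.fdr_stratum or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _range_str(rng: Optional[tuple[int, int]]) -> str:
    # intervals are 0-based half-open internally; the table boundary
    # renders them 1-based inclusive
    return "" if rng is None else f"{rng[0] + 1}-{rng[1]}"


def _parse_range(cell: str) -> Optional[tuple[int, int]]:
    if not cell:
        return None
    a, b = cell.split("-")
    return int(a) - 1, int(b)


def write_precursor_table(
    precursors: Iterable[PrecursorModel], path: Union[str, Path]
) -> None:
    rows = [
        {
            "transcript_id": p.transcript_id,
            "signal": _range_str(p.signal_range),
            "propeptide": _range_str(p.propeptide_range),
            "mature": _range_str(p.mature_range),
            "cterm_propeptide": _range_str(p.cterm_propeptide_range),
            "amidated": int(p.amidated),
            "disulfide_bonds": p.disulfide_bond_count,
            "completeness": p.cds_completeness,
        }
        for p in precursors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_precursor_table(
    path: Union[str, Path], sequences: Mapping[str, str]
) -> list[PrecursorModel]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        tid = row["transcript_id"]
        if tid not in sequences:
            raise ValueError(f"{path}: no sequence for {tid}")
        out.append(
            PrecursorModel(
                transcript_id=tid,
                full_sequence=sequences[tid],
                signal_range=_parse_range(str(row.get("signal", ""))),
                propeptide_range=_parse_range(str(row.get("propeptide", ""))),
                mature_range=_parse_range(str(row.get("mature", ""))),
                cterm_propeptide_range=_parse_range(
                    str(row.get("cterm_propeptide", ""))
                ),
                amidated=bool(int(row.get("amidated", 0))),
                disulfide_bond_count=int(row.get("disulfide_bonds", 0)),
                cds_completeness=row.get("completeness", "complete"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _rt_str(rt_bin: tuple[float, float]) -> str:
    return f"{rt_bin[0]:g}-{rt_bin[1]:g}"


def render_match_report(matches: Sequence[MassMatch]) -> pd.DataFrame:
    """Intact-mass match table: id, theoretical, experimental, RT range."""
    return pd.DataFrame(
        [
            {
                "Transcriptome ID": m.peptide_id,
                "Theoretical Mass": f"{m.theoretical_mass:.2f}",
                "Experimental Mass": f"{m.experimental_mass:.2f}",
                "RT Range": _rt_str(m.rt_bin),
            }
            for m in matches
        ],
        columns=["Transcriptome ID", "Theoretical Mass", "Experimental Mass",
                 "RT Range"],
    )


def render_coverage_report(
    reports: Sequence[CoverageReport], scores: Optional[Mapping[str, float]] = None
) -> pd.DataFrame:
    scores = scores or {}
    return pd.DataFrame(
        [
            {
                "Transcriptome ID": r.parent_id,
                "Score": scores.get(r.parent_id, ""),
                "Coverage": f"{r.coverage_percent:.1f}%",
            }
            for r in sorted(reports, key=lambda r: r.parent_id)
        ],
        columns=["Transcriptome ID", "Score", "Coverage"],
    )


def render_physchem_report(
    profiles: Sequence[tuple[str, str, PhyschemProfile]]
) -> pd.DataFrame:
    """(id, family label, profile) triples -> descriptor table."""
    return pd.DataFrame(
        [
            {
                "ID": pid,
                "Family": family,
                "Length of the Mature Peptide": prof.length,
                "Hydrophobicity": f"{prof.mean_hydrophobicity:.3f}",
                "Hydrophobic Moment": f"{prof.hydrophobic_moment:.3f}",
                "Charge": f"{prof.net_charge:+d}" if prof.net_charge else "0",
            }
            for pid, family, prof in profiles
        ],
        columns=["ID", "Family", "Length of the Mature Peptide",
                 "Hydrophobicity", "Hydrophobic Moment", "Charge"],
    )


def render_classification_report(
    names: Mapping[str, str], classifications: Mapping[str, object]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "name": names[tid],
                "family": getattr(classifications[tid], "family_code", ""),
                "subtype": getattr(classifications[tid], "subtype_code", ""),
            }
            for tid in sorted(names)
        ],
        columns=["transcript_id", "name", "family", "subtype"],
    )


def render_summary_report(summary: FingerprintSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "components": summary.count,
                "min_mass_da": f"{summary.min_mass:.2f}",
                "max_mass_da": f"{summary.max_mass:.2f}",
                "median_mass_da": f"{summary.median_mass:.2f}",
            }
        ]
    )


def go_tally(annotations: Sequence[tuple[str, str]]) -> dict[str, float]:
    """Fractions of annotated transcripts per top-level ontology root."""
    if not annotations:
        raise ValueError("no annotations")
    counts = {root: 0 for root in GO_ROOTS}
    for tid, root in annotations:
        if root not in counts:
            raise ValueError(f"unknown ontology root {root!r} for {tid}")
        counts[root] += 1
    total = len(annotations)
    return {root: counts[root] / total for root in GO_ROOTS}


def config_hash(config: Mapping) -> str:
    """Short stable digest embedded in report headers for provenance."""
    text = repr(sorted((str(k), str(v)) for k, v in config.items()))
    return hashlib.sha256(text.encode()).hexdigest()[:12]
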