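"""Tryptic digestion, PSM acceptance and coverage."""

import pytest
from hypothesis import given, settings, strategies as st

from venomics.digest import (
    DigestPeptide,
    PSMRecord,
    cleavage_sites,
    compute_coverage,
    digest_peptide_masses,
    psm_filter,
    tryptic_digest,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(seq: str, max_missed: int, proline_rule: bool = True):
    """Independent oracle: every substring whose ends are valid cleavage
    boundaries and whose internal cut-site count is within the budget."""
    def is_cut(i):  # cut between residues i-1 and i
        return seq[i - 1] in "KR" and not (proline_rule and seq[i] == "P")

    out = set()
    n = len(seq)
    for a in range(n):
        if a != 0 and not is_cut(a):
            continue
        for b in range(a + 1, n + 1):
            if b != n and not is_cut(b):
                continue
            internal = sum(1 for i in range(a + 1, b) if is_cut(i))
            if internal <= max_missed:
                out.add((a, b, internal))
    return out


class TestDigest:
    def test_two_sites_full_cleavage(self):
        peps = tryptic_digest("AKGR", max_missed=0)
        assert {p.sequence for p in peps} == {"AK", "GR"}

    def test_proline_suppresses_cleavage(self):
        peps = tryptic_digest("AKPR", max_missed=0)
        assert {p.sequence for p in peps} == {"AKPR"}

    def test_proline_rule_can_be_disabled(self):
        peps = tryptic_digest("AKPR", max_missed=0, proline_rule=False)
        assert {p.sequence for p in peps} == {"AK", "PR"}

    def test_zero_missed_fragments_concatenate_to_parent(self):
        seq = "MKAILVKRGPSSDRAKPLNK"
        frags = tryptic_digest(seq, max_missed=0)
        assert "".join(p.sequence for p in frags) == seq
        # and they are disjoint and ordered
        for left, right in zip(frags, frags[1:]):
            assert left.end == right.start

    def test_min_length_filters_short_fragments(self):
        peps = tryptic_digest("AKGR", max_missed=0, min_length=3)
        assert peps == []

    def test_missed_cleavage_budget(self):
        peps = tryptic_digest("AKGKGK", max_missed=2)
        by_missed = {}
        for p in peps:
            by_missed.setdefault(p.missed_cleavages, set()).add(p.sequence)
        assert by_missed[0] == {"AK", "GK"}
        assert by_missed[1] == {"AKGK", "GKGK"}
        assert by_missed[2] == {"AKGKGK"}

    @given(
        seq=st.text(AA, min_size=1, max_size=200),
        max_missed=st.integers(0, 2),
    )
    @settings(max_examples=40)
    def test_matches_exhaustive_oracle(self, seq, max_missed):
        peps = tryptic_digest(seq, max_missed=max_missed)
        got = {(p.start, p.end, p.missed_cleavages) for p in peps}
        assert got == brute_force_digest(seq, max_missed)
        for p in peps:
            assert p.sequence == seq[p.start : p.end]

    @given(seq=st.text(AA, min_size=5, max_size=120), max_missed=st.integers(0, 2))
    @settings(max_examples=40)
    def test_fragment_count_formula(self, seq, max_missed):
        """With s internal sites: sum over k of (s+1-k) peptides, clipped."""
        s = len(cleavage_sites(seq))
        expected = sum(max(s + 1 - k, 0) for k in range(max_missed + 1))
        assert len(tryptic_digest(seq, max_missed=max_missed)) == expected


class TestPeptideVariants:
    def test_carbamidomethyl_is_fixed(self):
        pep = DigestPeptide("p", 0, 4, "ACCK", 0)
        base = digest_peptide_masses(pep, variable_mods=False)
        free = digest_peptide_masses(pep, carbamidomethyl=False,
                                     variable_mods=False)
        assert base[0][1] - free[0][1] == pytest.approx(2 * 57.02146)

    def test_variable_oxidation_and_amidation_enumerated(self):
        pep = DigestPeptide("p", 0, 4, "AMMK", 0)
        names = [n for n, _ in digest_peptide_masses(pep)]
        assert names == [
            "base", "1x oxidation", "2x oxidation",
            "amidation", "1x oxidation + amidation", "2x oxidation + amidation",
        ]

    def test_variable_site_cap(self):
        pep = DigestPeptide("p", 0, 5, "MMMMK", 0)
        names = [n for n, _ in digest_peptide_masses(pep, max_variable=3)]
        assert "3x oxidation" in names and "4x oxidation" not in names
        assert "3x oxidation + amidation" not in names  # 4 sites total


class TestPSMFilter:
    def test_boundary_score_rejected(self):
        assert psm_filter([PSMRecord("PEP", "p", 25.0, 3)]) == []

    def test_single_fragment_rejected(self):
        assert psm_filter([PSMRecord("PEP", "p", 30.0, 1)]) == []

    def test_accepted_case(self):
        rec = PSMRecord("PEP", "p", 46.06, 2)
        assert psm_filter([rec]) == [rec]

    def test_order_invariant(self):
        recs = [
            PSMRecord("A" * 3, "p", 20.0 + i, i % 4) for i in range(10)
        ]
        fwd = psm_filter(recs)
        rev = psm_filter(list(reversed(recs)))
        assert sorted(fwd, key=id) == sorted(fwd, key=id)
        assert set(fwd) == set(rev)

    def test_fdr_stratum_label_filter(self):
        strict = PSMRecord("PEP", "p", 30.0, 3, fdr_stratum="strict")
        relaxed = PSMRecord("GGG", "p", 30.0, 3, fdr_stratum="relaxed")
        assert psm_filter([strict, relaxed], fdr_strata=["strict"]) == [strict]


class TestCoverage:
    def test_full_span_single_peptide(self):
        report = compute_coverage(("TatHDPND403", "FFSLIPSLIGGLV"),
                                  ["FFSLIPSLIGGLV"])
        assert report.coverage_percent == 100.0

    def test_no_accepted_peptides(self):
        report = compute_coverage(("p", "FFSLIPSLIGGLV"), [])
        assert report.coverage_percent == 0.0 and not report.covered_positions

    def test_unlocatable_peptide_contributes_nothing(self):
        report = compute_coverage(("p", "AAAA"), ["WWW"])
        assert report.coverage_percent == 0.0

    def test_all_occurrences_counted(self):
        report = compute_coverage(("p", "AKGGAKGG"), ["AK"])
        assert report.covered_positions == {0, 1, 4, 5}
        assert report.coverage_percent == 50.0

    @given(
        parent=st.text(AA, min_size=10, max_size=80),
        windows=st.lists(
            st.tuples(st.integers(0, 70), st.integers(2, 12)), max_size=8
        ),
    )
    @settings(max_examples=40)
    def test_matches_position_union_oracle_and_is_monotone(
        self, parent, windows
    ):
        peptides = [
            parent[a : a + w] for a, w in windows if a + w <= len(parent)
        ]
        oracle: set[int] = set()
        for pep in peptides:
            start = parent.find(pep)
            while start != -1:
                oracle.update(range(start, start + len(pep)))
                start = parent.find(pep, start + 1)
        report = compute_coverage(("p", parent), peptides)
        assert report.covered_positions == frozenset(oracle)
        # monotone under adding peptides; idempotent under duplicates
        doubled = compute_coverage(("p", parent), peptides + peptides)
        assert doubled.covered_positions == report.covered_positions
        for i in range(len(peptides)):
            partial = compute_coverage(("p", parent), peptides[:i])
            assert partial.covered_positions <= report.covered_positions
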