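"""Candidate triage, family classification, naming and tallies."""

from collections import Counter

import pytest
from hypothesis import given, strategies as st

from venomics.triage import (
    FAMILY_SUBTYPES,
    AnnotationEvidence,
    TriageConfig,
    VenomClassification,
    assign_names,
    classify_family,
    default_rulebook,
    tally_families,
    triage_transcript,
)


def _ev(tid="t1", est=(), dom=(), tox=(), desc=""):
    return AnnotationEvidence(
        transcript_id=tid,
        est_hits=list(est),
        domain_hits=list(dom),
        toxin_db_hits=list(tox),
        keyword_descriptor=desc,
    )


class TestTriage:
    def test_single_domain_hit_satisfies_criterion_2_only(self):
        res = triage_transcript(_ev(dom=[("PF00537", "Toxin_2 domain", 1e-10)]))
        assert res.is_candidate and res.satisfied_criteria == frozenset({2})

    def test_empty_evidence_is_not_a_candidate(self):
        res = triage_transcript(_ev())
        assert not res.is_candidate and not res.satisfied_criteria

    def test_each_criterion_flags_independently(self):
        assert triage_transcript(
            _ev(est=[("EST1", 95.0, 1e-20)])
        ).satisfied_criteria == frozenset({1})
        assert triage_transcript(
            _ev(tox=[("P01491", 60.0, 1e-8)])
        ).satisfied_criteria == frozenset({3})

    def test_evalue_cutoff_applies_to_every_criterion(self):
        weak = _ev(
            est=[("EST1", 95.0, 1e-3)],
            dom=[("PF1", "Toxin_2", 1e-3)],
            tox=[("P1", 60.0, 1e-3)],
        )
        assert not triage_transcript(weak).is_candidate
        assert triage_transcript(weak, TriageConfig(evalue_max=1e-2)).is_candidate

    def test_non_venom_domain_does_not_count(self):
        res = triage_transcript(_ev(dom=[("PF00001", "WD40 repeat", 1e-30)]))
        assert not res.is_candidate

    @given(
        base_hits=st.lists(
            st.tuples(
                st.sampled_from(["a", "b", "c"]),
                st.floats(0, 100),
                st.floats(1e-30, 1.0),
            ),
            max_size=4,
        ),
        extra=st.tuples(st.just("x"), st.floats(0, 100), st.floats(1e-30, 1e-5)),
    )
    def test_triage_is_monotone_in_evidence(self, base_hits, extra):
        """Adding a hit never flips a candidate back to non-candidate."""
        before = triage_transcript(_ev(tox=base_hits)).is_candidate
        after = triage_transcript(_ev(tox=base_hits + [extra])).is_candidate
        assert after >= before


class TestClassification:
    @pytest.mark.parametrize(
        "descriptor,family,subtype",
        [
            ("beta-toxin sodium channel", "NaT", "Bet"),
            ("scorpine", "KTx", "Scr"),
            ("unknown venom protein", "Oth", "Und"),
            ("calcin ryanodine receptor toxin", "CaT", "Clc"),
            ("ndbp-4 family antimicrobial peptide", "HDP", "ND4"),
            ("serpin serine protease inhibitor", "PIn", "Srp"),
            ("phospholipase a2", "Enz", "PA2"),
        ],
    )
    def test_rulebook_examples(self, descriptor, family, subtype):
        cls = classify_family(_ev(desc=descriptor))
        assert (cls.family_code, cls.subtype_code) == (family, subtype)

    def test_first_matching_rule_wins(self):
        # descriptor matches both the PA2 rule and (later) the serine
        # protease rule; order decides
        cls = classify_family(_ev(desc="phospholipase a2 serine protease"))
        assert cls.subtype_code == "PA2"

    def test_domain_names_participate_in_matching(self):
        cls = classify_family(_ev(dom=[("PF00068", "phospholipase a2", 1e-9)]))
        assert (cls.family_code, cls.subtype_code) == ("Enz", "PA2")

    def test_rulebook_subtypes_are_all_valid(self):
        for rule in default_rulebook():
            assert rule.subtype in FAMILY_SUBTYPES[rule.family]

    def test_invalid_subtype_for_family_rejected(self):
        with pytest.raises(ValueError):
            VenomClassification("Tat", "NaT", "Scr")


class TestNaming:
    def test_first_unregistered_gets_01(self):
        classified = {"c1": VenomClassification("Tat", "NaT", "Alp")}
        names = assign_names(classified, {"c1": "SEQ"})
        assert names == {"c1": "TatNaTAlp01"}

    def test_registered_sequence_keeps_published_name(self):
        classified = {
            "c1": VenomClassification("Tat", "HDP", "ND4"),
            "c2": VenomClassification("Tat", "HDP", "ND4"),
        }
        seqs = {"c1": "FFSLIPSLIGGLV", "c2": "AAAAKKKK"}
        names = assign_names(classified, seqs, {"FFSLIPSLIGGLV": "ViCT2"})
        assert names["c1"] == "ViCT2"
        assert names["c2"] == "TatHDPND401"  # serials skip the registered one

    def test_serials_follow_ascending_transcript_id(self):
        classified = {
            tid: VenomClassification("Tat", "KTx", "Alp")
            for tid in ("compB", "compA")
        }
        names = assign_names(classified, {})
        assert names == {"compA": "TatKTxAlp01", "compB": "TatKTxAlp02"}

    def test_idempotent_and_order_independent(self):
        classified = {
            f"c{i}": VenomClassification("Tat", "Enz", "SeP") for i in range(12)
        }
        a = assign_names(classified, {})
        b = assign_names(dict(reversed(list(classified.items()))), {})
        assert a == b == assign_names(classified, {})

    def test_two_digit_scheme_exhaustion_rejected(self):
        classified = {
            f"c{i:03d}": VenomClassification("Tat", "Enz", "SeP")
            for i in range(100)
        }
        with pytest.raises(ValueError, match="exhausted"):
            assign_names(classified, {})
        names = assign_names(classified, {}, index_width=3)
        assert names["c099"] == "TatEnzSeP100"


class TestTally:
    def test_empty_set_gives_all_zeros(self):
        tally = tally_families([])
        assert tally.total == 0
        assert all(v == 0 for v in tally.rollup.values())

    def test_dbp_rollup_merges_channel_toxin_families(self):
        classified = [
            VenomClassification("Tat", "NaT", "Alp"),
            VenomClassification("Tat", "KTx", "Scr"),
            VenomClassification("Tat", "CaT", "Clc"),
            VenomClassification("Tat", "Oth", "La1"),
        ]
        tally = tally_families(classified)
        assert tally.rollup["DBP"] == 3 and tally.rollup["La1"] == 1

    @given(
        labels=st.lists(
            st.sampled_from(
                [(f, s) for f, subs in FAMILY_SUBTYPES.items() for s in subs]
            ),
            max_size=60,
        )
    )
    def test_tally_matches_brute_force_count_and_conserves(self, labels):
        classified = [VenomClassification("Tat", f, s) for f, s in labels]
        tally = tally_families(classified)
        brute = Counter(labels)
        for key, n in brute.items():
            assert tally.by_subtype[key] == n
        assert sum(tally.by_subtype.values()) == tally.total == len(labels)
        assert sum(tally.by_family.values()) == len(labels)
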