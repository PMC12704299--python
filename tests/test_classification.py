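"""Allele keys, five-category taxonomy, summaries, rankings, arm contrast."""

import pytest

from ampedit.alignment import EventKind, IndelEvent
from ampedit.classification import (
    CATEGORIES,
    AlleleRecord,
    ClassifyParams,
    canonical_allele_key,
    classify_allele,
    collapse_reads,
    compare_arms,
    dash_notation,
    summarize,
    top_alleles,
)
from ampedit.microhomology import enumerate_microhomologies, predict_mmej_products

DEL = EventKind.DELETION
INS = EventKind.INSERTION
SUB = EventKind.SUBSTITUTION


def _allele(key, count, category, mmej=False, mh_len=0):
    return AlleleRecord(key, (), count, category, mmej, mh_len)


class TestAlleleKey:
    def test_empty_is_wt(self):
        assert canonical_allele_key([]) == "WT"

    def test_substitutions_do_not_define_alleles(self):
        subs = [IndelEvent(SUB, (5, 6), "A")]
        assert canonical_allele_key(subs) == "WT"

    def test_key_depends_only_on_indels(self):
        a = [IndelEvent(DEL, (76, 84))]
        b = [IndelEvent(DEL, (76, 84)), IndelEvent(SUB, (10, 11), "C")]
        assert canonical_allele_key(a) == canonical_allele_key(b)

    def test_distinct_events_distinct_keys(self):
        a = [IndelEvent(DEL, (76, 84))]
        b = [IndelEvent(DEL, (76, 85))]
        c = [IndelEvent(INS, (76, 76), "AT")]
        keys = {canonical_allele_key(x) for x in (a, b, c)}
        assert len(keys) == 3


class TestClassify:
    REF = "GCTA" * 40  # repeat-free junctions are irrelevant here

    def test_no_indels_is_wt(self):
        cat, mmej, mh = classify_allele([], (76, 81), self.REF)
        assert (cat, mmej, mh) == ("wt_or_sub", False, 0)

    def test_substitution_only_is_wt(self):
        events = [IndelEvent(SUB, (80, 81), "A")]
        assert classify_allele(events, (76, 81), self.REF)[0] == "wt_or_sub"

    def test_insertion_takes_precedence(self):
        events = [
            IndelEvent(INS, (78, 78), "TT"),
            IndelEvent(DEL, (80, 84)),
        ]
        assert classify_allele(events, (76, 81), self.REF)[0] == "insertion"

    def test_deletion_overlapping_window_is_on_position(self):
        events = [IndelEvent(DEL, (76, 84))]
        cat, _, _ = classify_allele(events, (76, 81), self.REF)
        assert cat == "deletion_on_position"

    def test_distal_deletion_is_off_position(self):
        events = [IndelEvent(DEL, (20, 21))]
        cat, mmej, _ = classify_allele(events, (76, 81), self.REF, ClassifyParams(pad=1))
        assert cat == "deletion_off_position" and not mmej

    def test_mmej_product_classified_mmej(self, toy_mh_reference):
        pairs = enumerate_microhomologies(toy_mh_reference, (7, 8), 8, 4)
        (prod,) = predict_mmej_products(pairs, toy_mh_reference)
        events = [IndelEvent(DEL, prod.deleted_interval)]
        cat, mmej, mh_len = classify_allele(events, (7, 8), toy_mh_reference)
        assert cat == "deletion_on_position"
        assert mmej is True
        assert mh_len == 4

    def test_ambiguity_expansion_pulls_slid_deletion_on_position(self):
        # deletion placed left of the window but slidable into it
        ref = "TTAGGCATCAGGCTAA"
        events = [IndelEvent(DEL, (2, 9))]  # equivalent placement of (6, 13)
        cat, _, _ = classify_allele(events, (11, 12), ref, ClassifyParams(pad=0))
        assert cat == "deletion_on_position"

    def test_mmej_flag_monotone_in_min_mh(self, toy_mh_reference):
        events = [IndelEvent(DEL, (6, 13))]
        flags = [
            classify_allele(
                events, (7, 8), toy_mh_reference, ClassifyParams(min_mh=m)
            )[1]
            for m in (1, 2, 4, 5, 8)
        ]
        assert flags == sorted(flags, reverse=True)  # True..True, False..False


class TestSummarize:
    def test_worked_arithmetic(self):
        alleles = [
            _allele("WT", 50, "wt_or_sub"),
            _allele("I1", 5, "insertion"),
            _allele("D1", 10, "deletion_on_position", mmej=True, mh_len=3),
            _allele("D2", 30, "deletion_on_position"),
            _allele("D3", 5, "deletion_off_position"),
        ]
        s = summarize(alleles)
        assert s.total_reads == 100
        assert s.fractions == {
            "wt_or_sub": 0.50,
            "insertion": 0.05,
            "deletion_on_position": 0.40,
            "deletion_off_position": 0.05,
        }
        assert s.mmej_fraction == 0.10
        assert s.editing_efficiency == 0.50

    def test_all_wt(self):
        s = summarize([_allele("WT", 7, "wt_or_sub")])
        assert s.editing_efficiency == 0.0
        assert s.fractions["wt_or_sub"] == 1.0

    def test_fractions_sum_to_one(self):
        s = summarize(
            [
                _allele("WT", 3, "wt_or_sub"),
                _allele("D1", 7, "deletion_off_position"),
            ]
        )
        assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no classified reads"):
            summarize([])


class TestTopAlleles:
    def test_all_indel_alleles_cover_all_indels(self):
        alleles = [
            _allele(f"D{i}", c, "deletion_on_position")
            for i, c in enumerate([40, 30, 20, 7, 3])
        ]
        top = top_alleles(alleles, 5)
        assert top.joint_indel_share == pytest.approx(1.0)
        assert list(top.table["read_count"]) == [40, 30, 20, 7, 3]

    def test_n_larger_than_allele_count(self):
        alleles = [_allele("D0", 5, "deletion_on_position")]
        assert len(top_alleles(alleles, 10).table) == 1

    def test_wt_only_empty_table(self):
        top = top_alleles([_allele("WT", 9, "wt_or_sub")], 5)
        assert top.table.empty
        assert top.joint_indel_share == 0.0

    def test_tie_broken_lexicographically(self):
        alleles = [
            _allele("D9", 5, "deletion_on_position"),
            _allele("D1", 5, "deletion_on_position"),
        ]
        assert list(top_alleles(alleles, 1).table["allele_key"]) == ["D1"]


class TestCompareArms:
    def test_identical_summaries_zero_difference(self):
        s = summarize([_allele("WT", 50, "wt_or_sub"), _allele("D", 50, "deletion_on_position")])
        df = compare_arms(s, s)
        assert (df["difference"] == 0).all()

    def test_on_position_contrast(self):
        a = summarize(
            [_allele("D", 906, "deletion_on_position"), _allele("WT", 94, "wt_or_sub")]
        )
        b = summarize(
            [_allele("D", 447, "deletion_on_position"), _allele("WT", 553, "wt_or_sub")]
        )
        df = compare_arms(a, b).set_index("category")
        assert df.loc["deletion_on_position", "difference"] == pytest.approx(0.459)

    def test_wilson_interval_closed_form(self):
        s = summarize(
            [_allele("WT", 50, "wt_or_sub"), _allele("D", 50, "deletion_off_position")]
        )
        df = compare_arms(s, s).set_index("category")
        assert df.loc["wt_or_sub", "ci_a_low"] == pytest.approx(0.4038, abs=2e-4)
        assert df.loc["wt_or_sub", "ci_a_high"] == pytest.approx(0.5962, abs=2e-4)


def test_collapse_reads_groups_equivalent_reads(toy_mh_reference):
    per_read = {
        "r1": (IndelEvent(DEL, (2, 9), normalized=True),),
        "r2": (IndelEvent(DEL, (2, 9), normalized=True),),
        "r3": (),
    }
    alleles = collapse_reads(per_read, (7, 8), toy_mh_reference)
    by_key = {a.allele_key: a for a in alleles}
    assert by_key["WT"].read_count == 1
    (indel_key,) = [k for k in by_key if k != "WT"]
    assert by_key[indel_key].read_count == 2
    assert by_key[indel_key].mmej is True


def test_dash_notation_marks_deleted_bases():
    ref = "AACCGGTT"
    events = (IndelEvent(DEL, (2, 5)), IndelEvent(INS, (7, 7), "TG"))
    assert dash_notation(ref, events) == "AA---GT[TG]T"
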