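"""Spectrum expansion, allele application, read simulation, ground truth."""

import numpy as np
import pytest
from scipy import stats

from ampedit.alignment import EventKind, IndelEvent
from ampedit.classification import classify_allele
from ampedit.pipeline import find_unique_site
from ampedit.refmodel import ASCAS12A, Guide
from ampedit.simulate import (
    AlleleSpec,
    SimSpec,
    SpectrumFixture,
    apply_allele,
    build_spectrum,
    simulate_reads,
)

CRAFT = Guide("CRAFT_crRNA", "GCCCTATCCTGGGTCCACTCG")


@pytest.fixture(scope="module")
def trbc_site(trbc_amplicon):
    ref_id, seq = trbc_amplicon
    return find_unique_site(CRAFT, seq, ASCAS12A, ref_id)


def _fixture(**kw):
    defaults = dict(
        name="t", wt=0.5, insertion=0.0,
        deletion_on_position=0.5, deletion_off_position=0.0, mmej=0.0,
    )
    defaults.update(kw)
    return SpectrumFixture(**defaults)


class TestApplyAllele:
    def test_wt_identity(self):
        allele = AlleleSpec("WT", (), 1.0, "wt_or_sub", False)
        assert apply_allele("ACGTACGT", allele) == "ACGTACGT"

    def test_deletion_surgery(self):
        allele = AlleleSpec(
            "D", (IndelEvent(EventKind.DELETION, (6, 13)),), 1.0,
            "deletion_on_position", False,
        )
        assert apply_allele("TTAGGCATCAGGCTAA", allele) == "TTAGGCTAA"

    def test_insertion(self):
        allele = AlleleSpec(
            "I", (IndelEvent(EventKind.INSERTION, (3, 3), "G"),), 1.0,
            "insertion", False,
        )
        assert apply_allele("ACGT", allele) == "ACGGT"

    def test_overlapping_events_rejected(self):
        allele = AlleleSpec(
            "bad",
            (
                IndelEvent(EventKind.DELETION, (2, 6)),
                IndelEvent(EventKind.DELETION, (4, 8)),
            ),
            1.0,
            "deletion_on_position",
            False,
        )
        with pytest.raises(ValueError, match="overlap"):
            apply_allele("ACGTACGTACGT", allele)


class TestBuildSpectrum:
    def test_frequencies_sum_to_one(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        spectrum = build_spectrum(_fixture(), seq, trbc_site.cut_window, seed=0)
        assert sum(a.frequency for a in spectrum) == pytest.approx(1.0, abs=1e-12)
        assert len(spectrum) >= 2

    def test_category_marginals_match_fixture(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        fx = _fixture(
            wt=0.046, insertion=0.001,
            deletion_on_position=0.906, deletion_off_position=0.047, mmej=0.11,
        )
        spectrum = build_spectrum(fx, seq, trbc_site.cut_window, seed=0)
        marg = {}
        mmej_marg = 0.0
        for a in spectrum:
            marg[a.category] = marg.get(a.category, 0.0) + a.frequency
            if a.mmej:
                mmej_marg += a.frequency
        assert marg["wt_or_sub"] == pytest.approx(fx.wt)
        assert marg["insertion"] == pytest.approx(fx.insertion)
        assert marg["deletion_on_position"] == pytest.approx(fx.deletion_on_position)
        assert marg["deletion_off_position"] == pytest.approx(fx.deletion_off_position)
        assert mmej_marg == pytest.approx(fx.mmej)

    def test_truth_labels_agree_with_classifier(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        fx = _fixture(
            wt=0.25, insertion=0.25,
            deletion_on_position=0.25, deletion_off_position=0.25, mmej=0.1,
        )
        for a in build_spectrum(fx, seq, trbc_site.cut_window, seed=3):
            cat, mmej, _ = classify_allele(a.events, trbc_site.cut_window, seq)
            assert (cat, mmej) == (a.category, a.mmej)

    def test_mmej_on_repeat_free_reference_errors(self):
        # no repeat pair >= 2 nt straddles the cut at (8, 8)
        ref = "AATCTGTGTTAGCCCC"
        fx = _fixture(wt=0.5, deletion_on_position=0.5, mmej=0.2)
        with pytest.raises(ValueError, match="MMEJ"):
            build_spectrum(fx, ref, (8, 8), seed=0)

    def test_deterministic_under_seed(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        a = build_spectrum(_fixture(), seq, trbc_site.cut_window, seed=11)
        b = build_spectrum(_fixture(), seq, trbc_site.cut_window, seed=11)
        assert a == b


class TestSimulateReads:
    def _spec(self, seq, site, **kw):
        spectrum = build_spectrum(_fixture(), seq, site.cut_window, seed=5)
        defaults = dict(
            reference=seq, cut_window=site.cut_window, spectrum=spectrum,
            seed=9, n_reads=500, error_rate=0.0, mode="merged",
        )
        defaults.update(kw)
        return SimSpec(**defaults)

    def test_error_free_reads_reconstruct_alleles(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        spec = self._spec(seq, trbc_site)
        reads, _, truth = simulate_reads(spec)
        by_label = {a.label: apply_allele(seq, a) for a in spec.spectrum}
        for read, t in zip(reads, truth):
            assert read.seq == by_label[t.allele_label]

    def test_wt_share_within_binomial_bound(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        spec = self._spec(seq, trbc_site, n_reads=10_000, seed=1)
        _, _, truth = simulate_reads(spec)
        wt = sum(t.category == "wt_or_sub" for t in truth)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= wt <= hi

    def test_byte_identical_reruns(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        spec = self._spec(seq, trbc_site, error_rate=0.003)
        out1 = simulate_reads(spec)
        out2 = simulate_reads(spec)
        assert out1 == out2

    def test_paired_mode_reads_from_fragment_ends(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        from ampedit.seqio import revcomp

        spec = self._spec(seq, trbc_site, mode="paired_2x150")
        r1s, r2s, truth = simulate_reads(spec)
        by_label = {a.label: apply_allele(seq, a) for a in spec.spectrum}
        assert r2s is not None
        for r1, r2, t in zip(r1s, r2s, truth):
            frag = by_label[t.allele_label]
            assert r1.seq == frag[:150]
            assert r2.seq == revcomp(frag)[:150]
            assert t.truncated == (len(frag) < 150)

    def test_error_rate_produces_substitutions_only(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        spec = self._spec(seq, trbc_site, error_rate=0.05, n_reads=200)
        reads, _, truth = simulate_reads(spec)
        by_label = {a.label: apply_allele(seq, a) for a in spec.spectrum}
        n_err = 0
        for read, t in zip(reads, truth):
            frag = by_label[t.allele_label]
            assert len(read.seq) == len(frag)  # substitutions never change length
            n_err += sum(a != b for a, b in zip(read.seq, frag))
        assert n_err > 0

    def test_invalid_error_rate_rejected(self, trbc_amplicon, trbc_site):
        _, seq = trbc_amplicon
        with pytest.raises(ValueError):
            self._spec(seq, trbc_site, error_rate=0.5)
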