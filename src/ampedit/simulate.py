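"""Synthetic MiSeq-style amplicon read generator with per-read ground truth.

The generator and the analysis pipeline are deliberately independent code
paths: the generator *applies* indel events to the reference and emits reads
(optionally with i.i.d. per-base substitution errors), while the pipeline
must re-derive the events by alignment.  Every emitted read carries a truth
record (allele label, outcome category, MMEJ flag) so recovery can be
checked end to end.

A spectrum fixture gives category-level proportions (WT, insertion,
on-position deletion with an MMEJ sub-fraction, off-position deletion);
:func:`build_spectrum` expands these into concrete alleles — MMEJ deletions
taken from the enumerated microhomology products, non-MMEJ on-position
deletions, insertions at the cut, and distal deletions — each verified
against the classifier so truth labels are consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alignment import EventKind, IndelEvent, ReadRecord, apply_events
from .classification import ClassifyParams, DEFAULT_PARAMS, classify_allele
from .microhomology import enumerate_microhomologies, predict_mmej_products
from .seqio import revcomp, validate_dna

DEFAULT_N_READS = 20_000
DEFAULT_READ_LEN = 150
DEFAULT_QUALITY = 30

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleSpec:
    label: str
    events: tuple[IndelEvent, ...]  # empty = WT
    frequency: float
    category: str
    mmej: bool


@dataclass(frozen=True)
class SpectrumFixture:
    """Category-level outcome proportions (fractions of all reads)."""

    name: str
    wt: float
    insertion: float
    deletion_on_position: float
    deletion_off_position: float
    mmej: float  # subset of deletion_on_position

    def __post_init__(self) -> None:
        total = (
            self.wt
            + self.insertion
            + self.deletion_on_position
            + self.deletion_off_position
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fixture {self.name!r} proportions sum to {total}, not 1")
        if self.mmej > self.deletion_on_position + 1e-12:
            raise ValueError("mmej proportion exceeds deletion_on_position")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpectrumFixture":
        """Load a fixture file; category proportions are renormalized to sum
        to exactly 1 (printed percentages may carry rounding residue), the
        MMEJ sub-fraction scaled by the same factor."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cats = doc["categories"]
        total = sum(float(cats[c]) for c in
                    ("wt", "insertion", "deletion_on_position", "deletion_off_position"))
        if not 0.99 <= total <= 1.01:
            raise ValueError(f"fixture categories sum to {total}; expected ~1")
        return cls(
            name=str(doc.get("name", Path(path).stem)),
            wt=float(cats["wt"]) / total,
            insertion=float(cats["insertion"]) / total,
            deletion_on_position=float(cats["deletion_on_position"]) / total,
            deletion_off_position=float(cats["deletion_off_position"]) / total,
            mmej=float(doc.get("mmej", 0.0)) / total,
        )


@dataclass(frozen=True)
class SimSpec:
    reference: str
    cut_window: tuple[int, int]
    spectrum: tuple[AlleleSpec, ...]
    seed: int
    n_reads: int = DEFAULT_N_READS
    error_rate: float = 0.0
    mode: str = "merged"  # or "paired_2x150"
    read_len: int = DEFAULT_READ_LEN

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.mode not in ("merged", "paired_2x150"):
            raise ValueError(f"unknown mode {self.mode!r}")
        freq_sum = sum(a.frequency for a in self.spectrum)
        if abs(freq_sum - 1.0) > 1e-9:
            raise ValueError(f"spectrum frequencies sum to {freq_sum}, not 1")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    allele_label: str
    category: str
    mmej: bool
    truncated: bool = False


def apply_allele(reference: str, allele: AlleleSpec) -> str:
    """Edited amplicon sequence for one allele (WT returns the reference)."""
    return apply_events(reference, list(allele.events))


def _sample_distinct(
    make: "callable", accept: "callable", k: int, max_tries: int = 10_000
) -> list[tuple[IndelEvent, ...]]:
    out: list[tuple[IndelEvent, ...]] = []
    seen: set[tuple[IndelEvent, ...]] = set()
    tries = 0
    while len(out) < k:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not sample enough admissible alleles")
        cand = make()
        if cand in seen:
            continue
        if not accept(cand):
            continue
        seen.add(cand)
        out.append(cand)
    return out


def build_spectrum(
    fixture: SpectrumFixture,
    reference: str,
    cut_window: tuple[int, int],
    seed: int,
    params: ClassifyParams = DEFAULT_PARAMS,
    n_mmej_alleles: int = 3,
    n_on_alleles: int = 5,
    n_ins_alleles: int = 2,
    n_off_alleles: int = 3,
) -> tuple[AlleleSpec, ...]:
    """Expand category proportions into concrete alleles.

    MMEJ alleles are the top predicted microhomology deletion products;
    non-MMEJ on-position deletions are random 1-20 nt deletions overlapping
    the cut window with junction microhomology below ``params.min_mh``;
    insertions are random 1-10 nt sequences at the cut; off-position
    deletions sit at least ``params.pad + 5`` nt from the window.  Every
    allele is validated against :func:`classify_allele`, so generator truth
    and classifier taxonomy agree by construction.  Deterministic under
    ``seed``.
    """
    validate_dna(reference, what="reference")
    rng = np.random.default_rng(seed)
    n = len(reference)
    c0, c1 = cut_window
    pad = params.pad
    specs: list[AlleleSpec] = []

    def classify(events: tuple[IndelEvent, ...]) -> tuple[str, bool, int]:
        return classify_allele(events, cut_window, reference, params)

    if fixture.wt > 0:
        specs.append(AlleleSpec("WT", (), fixture.wt, "wt_or_sub", False))

    if fixture.mmej > 0:
        pairs = [
            p
            for p in enumerate_microhomologies(reference, cut_window, min_len=params.min_mh)
        ]
        products = predict_mmej_products(pairs, reference)
        usable = []
        for prod in products:
            ev = (IndelEvent(EventKind.DELETION, prod.deleted_interval),)
            cat, mmej, _ = classify(ev)
            if cat == "deletion_on_position" and mmej:
                usable.append(ev)
            if len(usable) == n_mmej_alleles:
                break
        if not usable:
            raise ValueError(
                "fixture requests MMEJ alleles but no microhomology pair "
                "yields an MMEJ-classified deletion at this cut"
            )
        share = fixture.mmej / len(usable)
        for i, ev in enumerate(usable):
            specs.append(AlleleSpec(f"MMEJ_{i + 1}", ev, share, "deletion_on_position", True))

    non_mmej_on = fixture.deletion_on_position - fixture.mmej
    if non_mmej_on > 1e-12:

        def make_on() -> tuple[IndelEvent, ...]:
            L = int(rng.integers(1, 21))
            lo = max(0, c0 - L)
            hi = min(c1, n - L)
            if hi < lo:
                return ()
            s = int(rng.integers(lo, hi + 1))
            return (IndelEvent(EventKind.DELETION, (s, s + L)),)

        def ok_on(ev: tuple[IndelEvent, ...]) -> bool:
            if not ev:
                return False
            cat, mmej, _ = classify(ev)
            return cat == "deletion_on_position" and not mmej

        events = _sample_distinct(make_on, ok_on, n_on_alleles)
        share = non_mmej_on / len(events)
        for i, ev in enumerate(events):
            specs.append(
                AlleleSpec(f"DEL_ON_{i + 1}", ev, share, "deletion_on_position", False)
            )

    if fixture.insertion > 0:

        def make_ins() -> tuple[IndelEvent, ...]:
            L = int(rng.integers(1, 11))
            p = int(rng.integers(c0, c1 + 1))
            alt = "".join(chr(b) for b in rng.choice(_BASES, size=L))
            return (IndelEvent(EventKind.INSERTION, (p, p), alt),)

        events = _sample_distinct(
            make_ins, lambda ev: classify(ev)[0] == "insertion", n_ins_alleles
        )
        share = fixture.insertion / len(events)
        for i, ev in enumerate(events):
            specs.append(AlleleSpec(f"INS_{i + 1}", ev, share, "insertion", False))

    if fixture.deletion_off_position > 0:
        margin = pad + 5

        def make_off() -> tuple[IndelEvent, ...]:
            L = int(rng.integers(1, 21))
            left_hi = c0 - margin - L
            right_lo = c1 + margin
            choices = []
            if left_hi >= 0:
                choices.append("left")
            if right_lo + L <= n:
                choices.append("right")
            if not choices:
                return ()
            side = choices[int(rng.integers(0, len(choices)))]
            if side == "left":
                s = int(rng.integers(0, left_hi + 1))
            else:
                s = int(rng.integers(right_lo, n - L + 1))
            return (IndelEvent(EventKind.DELETION, (s, s + L)),)

        def ok_off(ev: tuple[IndelEvent, ...]) -> bool:
            return bool(ev) and classify(ev)[0] == "deletion_off_position"

        events = _sample_distinct(make_off, ok_off, n_off_alleles)
        share = fixture.deletion_off_position / len(events)
        for i, ev in enumerate(events):
            specs.append(
                AlleleSpec(f"DEL_OFF_{i + 1}", ev, share, "deletion_off_position", False)
            )

    total = sum(s.frequency for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"spectrum frequencies sum to {total}")
    return tuple(specs)


def _mutate(seq_arr: np.ndarray, rng: np.random.Generator, error_rate: float) -> np.ndarray:
    """Apply i.i.d. substitution errors; each error draws one of the three
    other bases uniformly."""
    if error_rate <= 0:
        return seq_arr
    mask = rng.random(seq_arr.size) < error_rate
    k = int(mask.sum())
    if k == 0:
        return seq_arr
    out = seq_arr.copy()
    # shift by 1..3 positions in base order -> always a different base
    shifts = rng.integers(1, 4, size=k)
    idx_in_bases = np.searchsorted(_BASES, out[mask])
    out[mask] = _BASES[(idx_in_bases + shifts) % 4]
    return out


def simulate_reads(
    spec: SimSpec,
) -> tuple[list[ReadRecord], list[ReadRecord] | None, list[TruthRecord]]:
    """Generate reads and truth records.

    Returns ``(reads, r2_reads, truth)``: in merged mode ``r2_reads`` is
    None and each read is the full (mutated) edited amplicon; in paired
    mode two ``read_len``-nt reads are taken from the fragment ends, the
    second reverse-complemented, and fragments shorter than ``read_len``
    yield truncated reads flagged in the truth table.  Byte-reproducible
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([a.frequency for a in spec.spectrum])
    freqs = freqs / freqs.sum()
    allele_seqs = [
        np.frombuffer(apply_allele(spec.reference, a).encode(), dtype=np.uint8)
        for a in spec.spectrum
    ]
    choice = rng.choice(len(spec.spectrum), size=spec.n_reads, p=freqs)
    quals: dict[int, tuple[int, ...]] = {}

    def qual(length: int) -> tuple[int, ...]:
        if length not in quals:
            quals[length] = tuple([DEFAULT_QUALITY] * length)
        return quals[length]

    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] | None = [] if spec.mode == "paired_2x150" else None
    truth: list[TruthRecord] = []
    for i in range(spec.n_reads):
        allele = spec.spectrum[choice[i]]
        frag = _mutate(allele_seqs[choice[i]], rng, spec.error_rate)
        frag_str = frag.tobytes().decode()
        read_id = f"sim_{i:06d}"
        truncated = False
        if spec.mode == "merged":
            reads1.append(ReadRecord(read_id, frag_str, qual(len(frag_str))))
        else:
            truncated = len(frag_str) < spec.read_len
            r1 = frag_str[: spec.read_len]
            r2 = revcomp(frag_str)[: spec.read_len]
            reads1.append(ReadRecord(read_id, r1, qual(len(r1))))
            reads2.append(ReadRecord(read_id, r2, qual(len(r2))))  # type: ignore[union-attr]
        truth.append(
            TruthRecord(read_id, allele.label, allele.category, allele.mmej, truncated)
        )
    return reads1, reads2, truth


def truth_table(truth: list[TruthRecord]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "allele_label": t.allele_label,
                "category": t.category,
                "mmej": t.mmej,
                "truncated": t.truncated,
            }
            for t in truth
        ]
    )
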