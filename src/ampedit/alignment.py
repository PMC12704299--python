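"""Read preprocessing, global alignment and left-normalized indel calling.

Each amplicon read is aligned end-to-end against the reference with an
affine-gap Needleman-Wunsch (Gotoh) alignment, computed by
:class:`Bio.Align.PairwiseAligner`.  The default scores (match +2, mismatch
-2, gap open -6, gap extend -1; the opening penalty is charged on the first
gapped base, so a length-L gap costs ``6 + (L - 1)``) favour one long
deletion over scattered mismatches, which is the expected signature of
nuclease-induced alleles.

Gap runs in the alignment become single :class:`IndelEvent` objects and are
left-normalized: every indel is shifted to the smallest reference coordinate
that preserves the read sequence, so reads carrying the same allele yield
identical event lists regardless of how the traceback placed the gap inside
a repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from Bio import Align
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .seqio import _open_text, revcomp, validate_dna

DEFAULT_MIN_READ_LEN = 50
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_MIN_IDENTITY = 0.6


class EventKind(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    SUBSTITUTION = "substitution"


@dataclass(frozen=True, order=True)
class IndelEvent:
    """One alignment difference against the reference.

    ``ref_interval`` is 0-based half-open; width 0 for insertions (the gap
    coordinate where the bases are inserted), width >= 1 for deletions and
    substitutions.  ``alt_seq`` holds inserted bases (insertion) or the read
    bases (substitution) and is empty for deletions.
    """

    kind: EventKind = field(compare=False)
    ref_interval: tuple[int, int]
    alt_seq: str = ""
    normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.ref_interval
        if self.kind is EventKind.DELETION and (hi - lo < 1 or self.alt_seq):
            raise ValueError("deletion must have width >= 1 and empty alt_seq")
        if self.kind is EventKind.INSERTION and (hi != lo or not self.alt_seq):
            raise ValueError("insertion must have width 0 and non-empty alt_seq")

    @property
    def is_indel(self) -> bool:
        return self.kind is not EventKind.SUBSTITUTION


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    quals: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -6.0  # charged on the first base of a gap
    gap_extend: float = -1.0


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    score: float
    ref_aln: str
    read_aln: str
    events: tuple[IndelEvent, ...]
    identity: float


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def global_align(
    read: str | ReadRecord,
    reference: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AlignedRead:
    """Optimal global alignment of a read against the reference, with events
    called and left-normalized."""
    record = read if isinstance(read, ReadRecord) else ReadRecord("read", read)
    validate_dna(record.seq, allow_n=True, what=f"read {record.id!r}")
    validate_dna(reference, allow_n=True, what="reference")
    aln = _aligner(scoring).align(reference, record.seq)[0]
    ref_aln, read_aln = str(aln[0]), str(aln[1])
    events = call_indels_from_strings(ref_aln, read_aln)
    matches = sum(a == b and a != "-" for a, b in zip(ref_aln, read_aln))
    return AlignedRead(
        read_id=record.id,
        score=float(aln.score),
        ref_aln=ref_aln,
        read_aln=read_aln,
        events=tuple(events),
        identity=matches / len(ref_aln),
    )


def call_indels(aln: AlignedRead) -> list[IndelEvent]:
    """Events of an alignment (already normalized at construction)."""
    return list(aln.events)


def call_indels_from_strings(ref_aln: str, read_aln: str) -> list[IndelEvent]:
    """Parse a gapped alignment pair into left-normalized events.

    Contiguous gap runs collapse into single insertion/deletion events;
    substitutions are recorded per base and never merged with gaps.
    """
    if len(ref_aln) != len(read_aln):
        raise ValueError("gapped strings must have equal length")
    reference = ref_aln.replace("-", "")
    raw: list[IndelEvent] = []
    ref_pos = 0
    i = 0
    ncol = len(ref_aln)
    while i < ncol:
        r, q = ref_aln[i], read_aln[i]
        if r == "-":  # insertion run
            j = i
            while j < ncol and ref_aln[j] == "-":
                j += 1
            raw.append(
                IndelEvent(
                    EventKind.INSERTION, (ref_pos, ref_pos), read_aln[i:j]
                )
            )
            i = j
        elif q == "-":  # deletion run
            j = i
            while j < ncol and read_aln[j] == "-" and ref_aln[j] != "-":
                j += 1
            width = j - i
            raw.append(
                IndelEvent(EventKind.DELETION, (ref_pos, ref_pos + width))
            )
            ref_pos += width
            i = j
        else:
            if r != q:
                raw.append(
                    IndelEvent(EventKind.SUBSTITUTION, (ref_pos, ref_pos + 1), q)
                )
            ref_pos += 1
            i += 1
    return normalize_events(raw, reference)


def normalize_events(
    events: list[IndelEvent], reference: str
) -> list[IndelEvent]:
    """Left-shift every indel to its smallest reference coordinate that
    preserves the read sequence.  Shifts never cross another event, so
    applying the normalized events still reconstructs the read.  Idempotent.
    """
    events = sorted(events, key=lambda e: (e.ref_interval, e.kind.value))
    out: list[IndelEvent] = []
    prev_end = 0
    for ev in events:
        if ev.kind is EventKind.DELETION:
            d0, d1 = ev.ref_interval
            while d0 > prev_end and reference[d0 - 1] == reference[d1 - 1]:
                d0 -= 1
                d1 -= 1
            out.append(replace(ev, ref_interval=(d0, d1), normalized=True))
            prev_end = d1
        elif ev.kind is EventKind.INSERTION:
            p = ev.ref_interval[0]
            alt = ev.alt_seq
            while p > prev_end and reference[p - 1] == alt[-1]:
                alt = alt[-1] + alt[:-1]
                p -= 1
            out.append(
                replace(ev, ref_interval=(p, p), alt_seq=alt, normalized=True)
            )
            prev_end = p
        else:
            out.append(replace(ev, normalized=True))
            prev_end = ev.ref_interval[1]
    out.sort(key=lambda e: (e.ref_interval, e.kind.value))
    return out


def apply_events(reference: str, events: list[IndelEvent]) -> str:
    """Reconstruct the read implied by a set of non-overlapping events."""
    ordered = sorted(events, key=lambda e: e.ref_interval)
    parts: list[str] = []
    pos = 0
    for ev in ordered:
        lo, hi = ev.ref_interval
        if lo < pos:
            raise ValueError(f"overlapping events at reference position {lo}")
        parts.append(reference[pos:lo])
        if ev.kind is EventKind.DELETION:
            pos = hi
        elif ev.kind is EventKind.INSERTION:
            parts.append(ev.alt_seq)
            pos = lo
        else:
            parts.append(ev.alt_seq)
            pos = hi
    parts.append(reference[pos:])
    return "".join(parts)


def qc_filter(
    reads: list[ReadRecord], min_len: int = DEFAULT_MIN_READ_LEN
) -> tuple[list[ReadRecord], int]:
    """Drop reads shorter than ``min_len``; returns (kept, discarded count)."""
    kept = [r for r in reads if len(r.seq) >= min_len]
    return kept, len(reads) - len(kept)


def merge_read_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> ReadRecord | None:
    """Merge a read pair by its best ungapped 3' overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    first.  Overlaps of length >= ``min_overlap`` with at most
    ``max_mismatch_frac`` disagreement are scored by (matches - mismatches);
    the consensus takes the higher-quality base at conflicts (ties go to
    r1).  Returns None when no admissible overlap exists.
    """
    seq2 = revcomp(r2.seq)
    quals2 = tuple(reversed(r2.quals)) if r2.quals is not None else None
    best: tuple[float, int] | None = None
    for o in range(min(len(r1.seq), len(seq2)), min_overlap - 1, -1):
        tail = r1.seq[-o:]
        head = seq2[:o]
        mism = sum(a != b for a, b in zip(tail, head))
        if mism / o > max_mismatch_frac:
            continue
        score = (o - mism) - mism
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return None
    o = best[1]
    left = r1.seq[: len(r1.seq) - o]
    right = seq2[o:]
    mid = []
    mid_quals = []
    for k in range(o):
        i1 = len(r1.seq) - o + k
        b1, b2 = r1.seq[i1], seq2[k]
        q1 = r1.quals[i1] if r1.quals is not None else 0
        q2 = quals2[k] if quals2 is not None else 0
        if b1 == b2:
            mid.append(b1)
            mid_quals.append(max(q1, q2))
        elif q2 > q1:
            mid.append(b2)
            mid_quals.append(q2)
        else:
            mid.append(b1)
            mid_quals.append(q1)
    merged_seq = left + "".join(mid) + right
    quals: tuple[int, ...] | None = None
    if r1.quals is not None and quals2 is not None:
        quals = (
            r1.quals[: len(r1.seq) - o] + tuple(mid_quals) + quals2[o:]
        )
    return ReadRecord(id=r1.id, seq=merged_seq, quals=quals)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a FASTQ file (.gz allowed) into ReadRecords."""
    reads = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append(
                ReadRecord(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    quals=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    return reads


def write_fastq(path: str | Path, reads: list[ReadRecord]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(
            r.quals if r.quals is not None else [30] * len(r.seq)
        )
        records.append(rec)
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")
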