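"""PAM-constrained, mismatch-bounded off-target scanning with feature
annotation.

The scan follows the Cas-OFFinder convention: a candidate site must carry an
exact (IUPAC) PAM match, and mismatches are counted over the protospacer
only, up to a configurable budget; bulges are not modelled.  N in the
database matches nothing (conservative).  Hits overlapping exon intervals
are annotated exonic, hits inside gene bodies intronic, everything else
intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pyranges as pr
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from .refmodel import Guide, IUPAC_CLASSES, NucleaseProfile, PamSide, Strand
from .seqio import revcomp, validate_dna


@dataclass(frozen=True)
class OffTargetHit:
    sequence_id: str
    strand: Strand
    site_interval: tuple[int, int]  # protospacer, 0-based half-open, plus strand
    mismatch_count: int
    site_seq: str  # protospacer in guide orientation
    pam_seq: str  # PAM in guide orientation
    on_target: bool
    annotation: str = "intergenic"
    feature_name: str | None = None


@dataclass(frozen=True)
class FeatureTrack:
    """Exon and gene-body intervals used to annotate hits.

    ``intervals`` holds (sequence_id, start, end, kind, name) with 0-based
    half-open coordinates; ``kind`` is "exon" or "gene".
    """

    intervals: tuple[tuple[str, int, int, str, str], ...]

    @classmethod
    def from_bed(cls, path: str | Path, feature_kind: str = "exon") -> "FeatureTrack":
        """BED intervals (0-based half-open; dialect: BED as read)."""
        df = pr.read_bed(str(path)).df
        rows = [
            (str(r.Chromosome), int(r.Start), int(r.End), feature_kind,
             str(getattr(r, "Name", "")) or "")
            for r in df.itertuples()
        ]
        return cls(intervals=tuple(rows))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "FeatureTrack":
        """GFF3 features (1-based inclusive on disk; converted to 0-based
        half-open on read).  ``exon`` records become exons; ``gene``/``mRNA``
        records become gene bodies."""
        df = pr.read_gff3(str(path)).df
        rows = []
        for r in df.itertuples():
            feat = str(r.Feature)
            if feat == "exon":
                kind = "exon"
            elif feat in ("gene", "mRNA"):
                kind = "gene"
            else:
                continue
            name = ""
            for attr in ("Name", "ID", "Parent"):
                val = getattr(r, attr, None)
                if isinstance(val, str) and val:
                    name = val
                    break
            rows.append((str(r.Chromosome), int(r.Start), int(r.End), kind, name))
        return cls(intervals=tuple(rows))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _pam_ok(windows: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean per window: PAM satisfies the IUPAC pattern; N in the
    database never matches."""
    ok = np.ones(windows.shape[0], dtype=bool)
    for k, code in enumerate(pattern):
        allowed = IUPAC_CLASSES[code] - {"N"}
        col = windows[:, k]
        member = np.zeros(windows.shape[0], dtype=bool)
        for base in allowed:
            member |= col == ord(base)
        ok &= member
    return ok


def _scan_strand(
    seq: str, spacer: str, profile: NucleaseProfile, max_mm: int
) -> list[tuple[int, int]]:
    """(site_start, mismatches) for one oriented sequence string, site
    coordinates local to that orientation."""
    L = len(spacer)
    plen = profile.pam_len
    n = len(seq)
    if n < L + plen:
        return []
    arr = _encode(seq)
    spacer_arr = _encode(spacer)
    wins = sliding_window_view(arr, L)  # starts 0..n-L
    mism = (wins != spacer_arr).sum(axis=1)
    # N in the database counts as mismatch via inequality; additionally it
    # must never *match*, which inequality already guarantees (spacer is ACGT).
    pam_wins = sliding_window_view(arr, plen)
    pam_good = _pam_ok(pam_wins, profile.pam_pattern)
    hits = []
    if profile.pam_side is PamSide.THREE_PRIME:
        starts = np.arange(0, n - L - plen + 1)
        valid = (mism[starts] <= max_mm) & pam_good[starts + L]
    else:
        starts = np.arange(plen, n - L + 1)
        valid = (mism[starts] <= max_mm) & pam_good[starts - plen]
    for s in starts[valid]:
        hits.append((int(s), int(mism[s])))
    return hits


def scan_offtargets(
    guide: Guide,
    database: dict[str, str],
    profile: NucleaseProfile,
    max_mm: int = 4,
) -> list[OffTargetHit]:
    """Every position/strand in ``database`` where the PAM matches exactly
    and the protospacer is within ``max_mm`` Hamming mismatches of the
    guide.  Exact matches are included and flagged on-target.  Hits sorted
    by (sequence_id, plus-strand start, plus before minus)."""
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    guide.validate_for(profile)
    spacer = guide.spacer
    L = len(spacer)
    plen = profile.pam_len
    hits: list[OffTargetHit] = []
    for seq_id in database:
        seq = database[seq_id]
        validate_dna(seq, allow_n=True, what=f"database sequence {seq_id!r}")
        n = len(seq)
        for strand in (Strand.PLUS, Strand.MINUS):
            oriented = seq if strand is Strand.PLUS else revcomp(seq)
            for s, mm in _scan_strand(oriented, spacer, profile, max_mm):
                if strand is Strand.PLUS:
                    iv = (s, s + L)
                else:
                    iv = (n - s - L, n - s)
                site = oriented[s : s + L]
                if profile.pam_side is PamSide.THREE_PRIME:
                    pam = oriented[s + L : s + L + plen]
                else:
                    pam = oriented[s - plen : s]
                hits.append(
                    OffTargetHit(
                        sequence_id=seq_id,
                        strand=strand,
                        site_interval=iv,
                        mismatch_count=mm,
                        site_seq=site,
                        pam_seq=pam,
                        on_target=(mm == 0),
                    )
                )
    hits.sort(
        key=lambda h: (h.sequence_id, h.site_interval[0], h.strand is Strand.MINUS)
    )
    return hits


def annotate_hits(
    hits: list[OffTargetHit], track: FeatureTrack
) -> list[OffTargetHit]:
    """Assign exonic > intronic > intergenic annotation by overlap of the
    protospacer interval with exon, then gene-body, intervals."""
    exons: dict[str, IntervalTree] = {}
    genes: dict[str, IntervalTree] = {}
    for seq_id, start, end, kind, name in track.intervals:
        if end <= start:
            raise ValueError(f"empty feature interval on {seq_id}: [{start}, {end})")
        tree = (exons if kind == "exon" else genes).setdefault(seq_id, IntervalTree())
        tree[start:end] = name
    out = []
    for h in hits:
        lo, hi = h.site_interval
        exon_hits = exons.get(h.sequence_id, IntervalTree())[lo:hi]
        if exon_hits:
            name = sorted(iv.data for iv in exon_hits)[0]
            out.append(replace(h, annotation="exonic", feature_name=name or None))
            continue
        gene_hits = genes.get(h.sequence_id, IntervalTree())[lo:hi]
        if gene_hits:
            name = sorted(iv.data for iv in gene_hits)[0]
            out.append(replace(h, annotation="intronic", feature_name=name or None))
            continue
        out.append(replace(h, annotation="intergenic", feature_name=None))
    return out


def hits_table(hits: list[OffTargetHit]) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        {
            "sequence_id": h.sequence_id,
            "strand": h.strand.value,
            "start_1based": h.site_interval[0] + 1,
            "end_1based": h.site_interval[1],
            "site": h.site_seq,
            "pam": h.pam_seq,
            "mismatches": h.mismatch_count,
            "on_target": h.on_target,
            "annotation": h.annotation,
            "gene": h.feature_name or "",
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "strand",
            "start_1based",
            "end_1based",
            "site",
            "pam",
            "mismatches",
            "on_target",
            "annotation",
            "gene",
        ],
    )
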