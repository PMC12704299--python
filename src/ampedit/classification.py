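"""Allele collapsing and five-category repair-outcome classification.

Reads are collapsed to alleles by a canonical key over their normalized
indel events (substitutions do not define alleles).  Each allele is assigned
to one of four mutually exclusive categories —

* ``wt_or_sub``              unedited or substitution-only reads,
* ``insertion``              any allele carrying an insertion,
* ``deletion_on_position``   a deletion whose (repeat-ambiguity-expanded)
                             interval intersects the predicted cut window,
* ``deletion_off_position``  deletions elsewhere on the amplicon —

and on-position deletions with junction microhomology of at least
``min_mh`` nt are additionally flagged MMEJ, splitting the on-position
slice into MMEJ and non-MMEJ repair.  The editing efficiency is the
fraction of reads carrying any indel (1 - WT fraction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .alignment import EventKind, IndelEvent
from .microhomology import junction_microhomology

CATEGORIES = (
    "wt_or_sub",
    "insertion",
    "deletion_on_position",
    "deletion_off_position",
)


@dataclass(frozen=True)
class ClassifyParams:
    """Tunable thresholds of the outcome taxonomy.

    pad
        Slack (nt) added around the cut window before testing intersection;
        absorbs residual alignment jitter at the junction.
    min_mh
        Minimum junction microhomology (nt) for an on-position deletion to
        count as MMEJ repair.
    """

    pad: int = 1
    min_mh: int = 2


DEFAULT_PARAMS = ClassifyParams()


@dataclass(frozen=True)
class AlleleRecord:
    allele_key: str
    events: tuple[IndelEvent, ...]
    read_count: int
    category: str
    mmej: bool
    mh_len: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.mmej and self.category != "deletion_on_position":
            raise ValueError("mmej flag requires deletion_on_position category")


@dataclass(frozen=True)
class ClassificationSummary:
    total_reads: int
    counts: dict[str, int]
    fractions: dict[str, float]
    mmej_fraction: float
    editing_efficiency: float


def canonical_allele_key(events: list[IndelEvent] | tuple[IndelEvent, ...]) -> str:
    """Deterministic key over the normalized indel events of a read.

    Substitutions are excluded (they do not define alleles); the empty
    event list maps to "WT".
    """
    parts = []
    for ev in sorted(e for e in events if e.is_indel):
        lo, hi = ev.ref_interval
        if ev.kind is EventKind.DELETION:
            parts.append(f"D{lo}:{hi}")
        else:
            parts.append(f"I{lo}+{ev.alt_seq}")
    return ";".join(parts) if parts else "WT"


def classify_allele(
    events: list[IndelEvent] | tuple[IndelEvent, ...],
    cut_window: tuple[int, int],
    reference: str,
    params: ClassifyParams = DEFAULT_PARAMS,
) -> tuple[str, bool, int]:
    """Category, MMEJ flag and junction-microhomology length of one allele.

    Precedence: no indel -> wt_or_sub; any insertion -> insertion; any
    deletion whose ambiguity-expanded interval (all equivalent placements of
    the same deletion, padded by ``params.pad``) intersects ``cut_window``
    -> deletion_on_position; otherwise deletion_off_position.
    """
    indels = [e for e in events if e.is_indel]
    if not indels:
        return "wt_or_sub", False, 0
    if any(e.kind is EventKind.INSERTION for e in indels):
        return "insertion", False, 0
    c0, c1 = cut_window
    on_mh: list[int] = []
    all_mh: list[int] = []
    for ev in indels:
        d0, d1 = ev.ref_interval
        mh_len, (a0, _) = junction_microhomology(reference, (d0, d1))
        all_mh.append(mh_len)
        lo = a0 - params.pad
        hi = a0 + mh_len + (d1 - d0) + params.pad
        if lo <= c1 and hi >= c0:
            on_mh.append(mh_len)
    if on_mh:
        mh = max(on_mh)
        return "deletion_on_position", mh >= params.min_mh, mh
    return "deletion_off_position", False, max(all_mh)


def collapse_reads(
    per_read_events: dict[str, tuple[IndelEvent, ...]],
    cut_window: tuple[int, int],
    reference: str,
    params: ClassifyParams = DEFAULT_PARAMS,
) -> list[AlleleRecord]:
    """Group reads by canonical allele key and classify each allele once.

    ``per_read_events`` maps read id -> normalized events.  Returns alleles
    sorted by read count descending, key ascending.
    """
    groups: dict[str, list[tuple[IndelEvent, ...]]] = {}
    for events in per_read_events.values():
        key = canonical_allele_key(events)
        groups.setdefault(key, []).append(events)
    alleles = []
    for key, members in groups.items():
        indels = tuple(sorted(e for e in members[0] if e.is_indel))
        category, mmej, mh_len = classify_allele(indels, cut_window, reference, params)
        alleles.append(
            AlleleRecord(
                allele_key=key,
                events=indels,
                read_count=len(members),
                category=category,
                mmej=mmej,
                mh_len=mh_len,
            )
        )
    alleles.sort(key=lambda a: (-a.read_count, a.allele_key))
    return alleles


def summarize(alleles: list[AlleleRecord]) -> ClassificationSummary:
    """Per-category read counts and fractions; exact rational arithmetic up
    to the final float conversion."""
    if not alleles:
        raise ValueError("no classified reads")
    counts = Counter({c: 0 for c in CATEGORIES})
    mmej_reads = 0
    for a in alleles:
        counts[a.category] += a.read_count
        if a.mmej:
            mmej_reads += a.read_count
    total = sum(counts.values())
    fractions = {c: Fraction(counts[c], total) for c in CATEGORIES}
    assert sum(fractions.values()) == 1
    return ClassificationSummary(
        total_reads=total,
        counts=dict(counts),
        fractions={c: float(f) for c, f in fractions.items()},
        mmej_fraction=float(Fraction(mmej_reads, total)),
        editing_efficiency=float(1 - fractions["wt_or_sub"]),
    )


@dataclass(frozen=True)
class TopAlleles:
    table: pd.DataFrame
    joint_indel_share: float  # share of indel-bearing reads held by the listed alleles


def top_alleles(alleles: list[AlleleRecord], n: int = 5) -> TopAlleles:
    """Top ``n`` indel-bearing alleles by read count (ties by key).

    Each row reports the allele's share of all reads and of indel-bearing
    reads; ``joint_indel_share`` is the summed indel share of the listed
    alleles (0 for WT-only input).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(a.read_count for a in alleles)
    indel_alleles = [a for a in alleles if a.allele_key != "WT"]
    indel_total = sum(a.read_count for a in indel_alleles)
    ranked = sorted(indel_alleles, key=lambda a: (-a.read_count, a.allele_key))[:n]
    rows = [
        {
            "allele_key": a.allele_key,
            "category": a.category,
            "mmej": a.mmej,
            "mh_len": a.mh_len,
            "read_count": a.read_count,
            "ratio_total": a.read_count / total if total else 0.0,
            "ratio_indel": a.read_count / indel_total if indel_total else 0.0,
        }
        for a in ranked
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "allele_key",
            "category",
            "mmej",
            "mh_len",
            "read_count",
            "ratio_total",
            "ratio_indel",
        ],
    )
    joint = sum(r["ratio_indel"] for r in rows)
    return TopAlleles(table=table, joint_indel_share=float(joint))


def dash_notation(reference: str, events: tuple[IndelEvent, ...]) -> str:
    """Render an allele against the reference with '-' marking each deleted
    nucleotide and insertions in brackets at their gap position."""
    out = []
    pos = 0
    for ev in sorted(events, key=lambda e: e.ref_interval):
        lo, hi = ev.ref_interval
        out.append(reference[pos:lo])
        if ev.kind is EventKind.DELETION:
            out.append("-" * (hi - lo))
            pos = hi
        elif ev.kind is EventKind.INSERTION:
            out.append(f"[{ev.alt_seq}]")
            pos = lo
        else:
            out.append(ev.alt_seq.lower())
            pos = hi
    out.append(reference[pos:])
    return "".join(out)


def alleles_table(
    alleles: list[AlleleRecord], reference: str
) -> pd.DataFrame:
    """Full allele table with dash-notation rendering, counts and shares."""
    total = sum(a.read_count for a in alleles)
    rows = [
        {
            "allele_key": a.allele_key,
            "rendering": dash_notation(reference, a.events),
            "category": a.category,
            "mmej": a.mmej,
            "mh_len": a.mh_len,
            "read_count": a.read_count,
            "fraction": a.read_count / total,
        }
        for a in alleles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "allele_key",
            "rendering",
            "category",
            "mmej",
            "mh_len",
            "read_count",
            "fraction",
        ],
    )


def compare_arms(
    a: ClassificationSummary, b: ClassificationSummary
) -> pd.DataFrame:
    """Per-category contrast of two arms: fraction difference, Wilson 95%
    CIs for each arm, and the two-proportion z statistic (pooled)."""
    rows = []
    for cat in CATEGORIES:
        xa, na = a.counts[cat], a.total_reads
        xb, nb = b.counts[cat], b.total_reads
        pa, pb = xa / na, xb / nb
        ci_a = proportion_confint(xa, na, alpha=0.05, method="wilson")
        ci_b = proportion_confint(xb, nb, alpha=0.05, method="wilson")
        pool = (xa + xb) / (na + nb)
        se = np.sqrt(pool * (1 - pool) * (1 / na + 1 / nb))
        z = (pa - pb) / se if se > 0 else 0.0
        rows.append(
            {
                "category": cat,
                "fraction_a": pa,
                "fraction_b": pb,
                "difference": pa - pb,
                "ci_a_low": ci_a[0],
                "ci_a_high": ci_a[1],
                "ci_b_low": ci_b[0],
                "ci_b_high": ci_b[1],
                "z": float(z),
            }
        )
    return pd.DataFrame(rows)
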