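"""End-to-end orchestration: QC -> merge -> align -> call -> classify ->
summarize -> rank, plus the guide-design report, with deterministic report
bundling and a key=value run log.

These functions are the library surface behind the command-line interface;
they accept in-memory objects or paths and write the tabular/JSON bundle.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .alignment import (
    DEFAULT_MAX_MISMATCH_FRAC,
    DEFAULT_MIN_IDENTITY,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_MIN_READ_LEN,
    DEFAULT_SCORING,
    AlignedRead,
    ReadRecord,
    ScoringScheme,
    global_align,
    merge_read_pair,
    qc_filter,
)
from .classification import (
    DEFAULT_PARAMS,
    AlleleRecord,
    ClassificationSummary,
    ClassifyParams,
    TopAlleles,
    alleles_table,
    collapse_reads,
    summarize,
    top_alleles,
)
from .microhomology import enumerate_microhomologies, microhomology_table
from .refmodel import (
    PROFILES,
    Guide,
    NucleaseProfile,
    TargetSite,
    locate_target,
    sites_table,
)


class PipelineError(RuntimeError):
    """User-facing pipeline failure (bad inputs, ambiguous target...)."""


class SummaryModel(BaseModel):
    """Machine-readable twin of the outcome pie: validated summary JSON."""

    reference_id: str
    guide_id: str
    profile: str
    total_reads: int
    merged_pairs: int | None = None
    merge_failures: int | None = None
    qc_discarded: int
    unassigned: int
    counts: dict[str, int]
    fractions_pct: dict[str, float]
    mmej_pct: float
    editing_efficiency_pct: float


@dataclass
class RunLog:
    lines: list[str] = field(default_factory=list)

    def record(self, **params: object) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        for key, value in params.items():
            self.lines.append(f"{stamp} {key}={value}")

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


@dataclass
class ProfileResult:
    site: TargetSite
    alleles: list[AlleleRecord]
    summary: ClassificationSummary
    top: TopAlleles
    unassigned: int
    qc_discarded: int
    merge_failures: int
    merged_pairs: int
    per_read: dict[str, tuple]


def _pct(x: float) -> float:
    return round(100.0 * x, 4)


def find_unique_site(
    guide: Guide, reference: str, profile: NucleaseProfile, reference_id: str = "ref"
) -> TargetSite:
    sites = locate_target(guide, reference, profile, reference_id)
    if len(sites) != 1:
        detail = "; ".join(
            f"{s.strand.value}[{s.protospacer_interval[0]},{s.protospacer_interval[1]})"
            for s in sites
        )
        raise PipelineError(
            f"expected exactly one target site for guide {guide.id!r}, "
            f"found {len(sites)}" + (f": {detail}" if detail else "")
        )
    return sites[0]


def analyze_reads(
    reads: list[ReadRecord],
    reference: str,
    cut_window: tuple[int, int],
    params: ClassifyParams = DEFAULT_PARAMS,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[AlleleRecord], ClassificationSummary, int, dict[str, tuple]]:
    """Align, call, classify and summarize a set of (merged) reads.

    Alignments are cached by read sequence — identical reads align
    identically — and reads below ``min_identity`` are excluded from the
    classification denominator as unassigned.  Returns (alleles, summary,
    unassigned count, per-read events).
    """
    cache: dict[str, AlignedRead] = {}
    per_read: dict[str, tuple] = {}
    unassigned = 0
    for read in reads:
        aln = cache.get(read.seq)
        if aln is None:
            aln = global_align(read.seq, reference, scoring)
            cache[read.seq] = aln
        if aln.identity < min_identity:
            unassigned += 1
            continue
        per_read[read.id] = aln.events
    if not per_read:
        raise PipelineError("no reads passed alignment identity filtering")
    alleles = collapse_reads(per_read, cut_window, reference, params)
    return alleles, summarize(alleles), unassigned, per_read


def run_profile(
    reference: str,
    reference_id: str,
    guide: Guide,
    profile: NucleaseProfile,
    reads1: list[ReadRecord],
    reads2: list[ReadRecord] | None = None,
    params: ClassifyParams = DEFAULT_PARAMS,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_len: int = DEFAULT_MIN_READ_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    top_n: int = 5,
) -> ProfileResult:
    """Full editing-outcome profile of one amplicon/guide/read set."""
    site = find_unique_site(guide, reference, profile, reference_id)
    merged_pairs = 0
    merge_failures = 0
    if reads2 is not None:
        if len(reads1) != len(reads2):
            raise PipelineError("paired input requires equally long R1/R2 lists")
        merged: list[ReadRecord] = []
        for r1, r2 in zip(reads1, reads2):
            m = merge_read_pair(r1, r2, min_overlap, max_mismatch_frac)
            if m is None:
                merge_failures += 1
            else:
                merged.append(m)
        merged_pairs = len(merged)
        reads = merged
    else:
        reads = reads1
    reads, qc_discarded = qc_filter(reads, min_len)
    if not reads:
        raise PipelineError("no reads left after QC filtering")
    alleles, summary, unassigned, per_read = analyze_reads(
        reads, reference, site.cut_window, params, scoring, min_identity
    )
    return ProfileResult(
        site=site,
        alleles=alleles,
        summary=summary,
        top=top_alleles(alleles, top_n),
        unassigned=unassigned,
        qc_discarded=qc_discarded,
        merge_failures=merge_failures,
        merged_pairs=merged_pairs,
        per_read=per_read,
    )


def summary_json(
    result: ProfileResult,
    reference_id: str,
    guide: Guide,
    profile: NucleaseProfile,
    paired: bool,
) -> SummaryModel:
    s = result.summary
    return SummaryModel(
        reference_id=reference_id,
        guide_id=guide.id,
        profile=profile.name,
        total_reads=s.total_reads,
        merged_pairs=result.merged_pairs if paired else None,
        merge_failures=result.merge_failures if paired else None,
        qc_discarded=result.qc_discarded,
        unassigned=result.unassigned,
        counts=s.counts,
        fractions_pct={c: _pct(f) for c, f in s.fractions.items()},
        mmej_pct=_pct(s.mmej_fraction),
        editing_efficiency_pct=_pct(s.editing_efficiency),
    )


def write_summary_schema(path: Path) -> None:
    path.write_text(json.dumps(SummaryModel.model_json_schema(), indent=2) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_profile_bundle(
    result: ProfileResult,
    reference: str,
    reference_id: str,
    guide: Guide,
    profile: NucleaseProfile,
    out_dir: Path,
    log: RunLog,
    paired: bool,
    per_read_events: bool = True,
) -> dict[str, Path]:
    """Write the report bundle: summary JSON, allele TSV, per-read TSV, MH
    TSV and the run log.  Deterministic float formatting (4 decimals)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    model = summary_json(result, reference_id, guide, profile, paired)
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(model.model_dump_json(indent=2) + "\n")

    paths["alleles"] = out_dir / "alleles.tsv"
    _write_tsv(alleles_table(result.alleles, reference), paths["alleles"])

    paths["top_alleles"] = out_dir / "top_alleles.tsv"
    _write_tsv(result.top.table, paths["top_alleles"])

    if per_read_events:
        from .alignment import EventKind

        rows = []
        for read_id, events in result.per_read.items():
            for ev in events:
                rows.append(
                    {
                        "read_id": read_id,
                        "kind": ev.kind.value,
                        "start_1based": ev.ref_interval[0] + 1,
                        "end_1based": ev.ref_interval[1],
                        "alt_seq": ev.alt_seq,
                    }
                )
        paths["per_read"] = out_dir / "per_read_events.tsv"
        _write_tsv(
            pd.DataFrame(
                rows, columns=["read_id", "kind", "start_1based", "end_1based", "alt_seq"]
            ),
            paths["per_read"],
        )

    mh_pairs = enumerate_microhomologies(reference, result.site.cut_window)
    paths["mh"] = out_dir / "microhomologies.tsv"
    _write_tsv(microhomology_table(mh_pairs), paths["mh"])

    paths["log"] = out_dir / "run.log"
    log.record(version=__version__)
    log.write(paths["log"])
    return paths


def run_design(
    reference: str,
    reference_id: str,
    guide: Guide,
    profile: NucleaseProfile,
    search_window: int = 30,
    min_mh: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guide-placement report: target-site table plus the microhomology
    table for each located site (empty tables when the guide is absent)."""
    sites = locate_target(guide, reference, profile, reference_id)
    site_df = sites_table(sites, reference)
    mh_frames = []
    for s in sites:
        pairs = enumerate_microhomologies(
            reference, s.cut_window, search_window=search_window, min_len=min_mh
        )
        df = microhomology_table(pairs)
        df.insert(0, "site_start_1based", s.protospacer_interval[0] + 1)
        mh_frames.append(df)
    mh_df = (
        pd.concat(mh_frames, ignore_index=True)
        if mh_frames
        else microhomology_table([])
    )
    return site_df, mh_df


def packaged_data(name: str) -> Path:
    """Path to a file shipped under ampedit/data."""
    return Path(resources.files("ampedit").joinpath("data", name))  # type: ignore[arg-type]
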