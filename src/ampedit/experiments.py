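"""Generator -> pipeline recovery experiments on the packaged TCR amplicons.

Each experiment builds a concrete allele spectrum from a packaged
category-proportion fixture, simulates amplicon reads with per-base
substitution errors, then runs the full analysis (align -> call ->
classify -> summarize) and returns both the recovered summary and the
simulated truth, so spectrum recovery can be quantified without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import ClassificationSummary, ClassifyParams, DEFAULT_PARAMS
from .pipeline import analyze_reads, find_unique_site, packaged_data
from .refmodel import PROFILES, Guide, TargetSite
from .seqio import read_fasta
from .simulate import (
    AlleleSpec,
    SimSpec,
    SpectrumFixture,
    TruthRecord,
    build_spectrum,
    simulate_reads,
)

#: The two packaged study arms: (guide id, spacer, profile, fixture file).
ARMS: dict[str, tuple[str, str, str, str]] = {
    "ascas12a_craft": (
        "CRAFT_crRNA",
        "GCCCTATCCTGGGTCCACTCG",
        "AsCas12a",
        "spectra/ascas12a_trbc.yaml",
    ),
    "spcas9_sgrna": (
        "TRBC_sgRNA",
        "GGAGAATGACGAGTGGACCC",
        "SpCas9",
        "spectra/spcas9_trbc.yaml",
    ),
}


@dataclass(frozen=True)
class RecoveryResult:
    arm: str
    site: TargetSite
    spectrum: tuple[AlleleSpec, ...]
    fixture: SpectrumFixture
    summary: ClassificationSummary
    truth: tuple[TruthRecord, ...]
    unassigned: int


def load_arm(arm: str) -> tuple[str, str, Guide, "object", SpectrumFixture]:
    """Reference (id, sequence), guide, profile and fixture for one arm."""
    guide_id, spacer, profile_name, fixture_rel = ARMS[arm]
    ref = read_fasta(packaged_data("trbc_amplicon.fa"))
    ((ref_id, ref_seq),) = ref.items()
    guide = Guide(guide_id, spacer)
    profile = PROFILES[profile_name]
    fixture = SpectrumFixture.from_yaml(packaged_data(fixture_rel))
    return ref_id, ref_seq, guide, profile, fixture


def recovery_experiment(
    arm: str,
    seed: int,
    n_reads: int = 20_000,
    error_rate: float = 0.001,
    params: ClassifyParams = DEFAULT_PARAMS,
) -> RecoveryResult:
    """Simulate one arm's reads and recover the outcome spectrum.

    The spectrum-construction and read-simulation stages draw from child
    seeds spawned from ``seed`` so the experiment is fully reproducible and
    the two stages are decoupled.
    """
    ref_id, ref_seq, guide, profile, fixture = load_arm(arm)
    site = find_unique_site(guide, ref_seq, profile, ref_id)
    child = np.random.SeedSequence(seed).spawn(2)
    spectrum_seed = int(child[0].generate_state(1)[0] % (2**31))
    sim_seed = int(child[1].generate_state(1)[0] % (2**31))
    spectrum = build_spectrum(
        fixture, ref_seq, site.cut_window, seed=spectrum_seed, params=params
    )
    spec = SimSpec(
        reference=ref_seq,
        cut_window=site.cut_window,
        spectrum=spectrum,
        seed=sim_seed,
        n_reads=n_reads,
        error_rate=error_rate,
        mode="merged",
    )
    reads, _, truth = simulate_reads(spec)
    _, summary, unassigned, _ = analyze_reads(
        reads, ref_seq, site.cut_window, params
    )
    return RecoveryResult(
        arm=arm,
        site=site,
        spectrum=spectrum,
        fixture=fixture,
        summary=summary,
        truth=tuple(truth),
        unassigned=unassigned,
    )
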