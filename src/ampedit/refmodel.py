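"""Nuclease chemistries, guide placement and double-strand-break prediction.

A :class:`NucleaseProfile` captures the geometry a Cas enzyme imposes on its
target: which side of the protospacer the PAM sits on, whether the cut is
blunt (SpCas9) or staggered with a 5' overhang (AsCas12a), and where on the
protospacer the strand cuts fall.  :func:`locate_target` finds every exact
protospacer occurrence of a guide on either strand of a reference amplicon
whose adjacent PAM satisfies the profile's IUPAC pattern, and
:func:`cut_positions` maps the chemistry's cut offsets into plus-strand gap
coordinates (positions *between* bases, 0-based).

Coordinate conventions: all intervals are 0-based half-open on the plus
strand; cut windows are inclusive pairs of gap coordinates.  Reports emit
1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .seqio import revcomp, validate_dna

# IUPAC nucleotide classes. A literal N in the *reference* is deliberately a
# member only of the pattern class N: an ambiguous reference base may satisfy
# "any base" but never a concrete requirement.
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}


class PamSide(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class CutGeometry(str, Enum):
    BLUNT = "blunt"
    STAGGERED = "staggered"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


@dataclass(frozen=True)
class NucleaseProfile:
    """Geometry of one nuclease chemistry.

    Parameters
    ----------
    pam_pattern
        IUPAC motif the PAM must satisfy, written 5'->3' on the protospacer
        strand.
    pam_side
        Side of the protospacer the PAM occupies, in protospacer orientation.
    spacer_len_range
        Inclusive (min, max) admissible spacer length in nt.
    cut_geometry
        Blunt (single cut coordinate) or staggered (two strand cuts giving a
        5' overhang).
    blunt_offset
        For blunt chemistry: distance of the cut from the PAM-proximal
        protospacer end, in nt (SpCas9 convention: 3, i.e. between
        protospacer positions 17 and 18 of a 20-mer counted from the
        PAM-distal end).
    stagger_offsets
        For staggered chemistry: (non-target-strand cut, target-strand cut)
        positions counted in nt from the PAM-proximal protospacer end.
        AsCas12a convention: (18, 23), a 5-nt 5' overhang.
    """

    name: str
    pam_pattern: str
    pam_side: PamSide
    spacer_len_range: tuple[int, int]
    cut_geometry: CutGeometry
    blunt_offset: int = 3
    stagger_offsets: tuple[int, int] = (18, 23)

    def __post_init__(self) -> None:
        if not self.pam_pattern:
            raise ValueError("pam_pattern must be non-empty")
        bad = set(self.pam_pattern) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(f"pam_pattern has non-IUPAC characters {sorted(bad)!r}")
        lo, hi = self.spacer_len_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid spacer_len_range {self.spacer_len_range}")
        if self.cut_geometry is CutGeometry.STAGGERED:
            if not self.stagger_offsets[0] < self.stagger_offsets[1]:
                raise ValueError(
                    "stagger_offsets must be strictly increasing "
                    f"(got {self.stagger_offsets})"
                )

    @property
    def pam_len(self) -> int:
        return len(self.pam_pattern)


SPCAS9 = NucleaseProfile(
    name="SpCas9",
    pam_pattern="NGG",
    pam_side=PamSide.THREE_PRIME,
    spacer_len_range=(17, 24),
    cut_geometry=CutGeometry.BLUNT,
    blunt_offset=3,
)

ASCAS12A = NucleaseProfile(
    name="AsCas12a",
    pam_pattern="TTTV",
    pam_side=PamSide.FIVE_PRIME,
    spacer_len_range=(18, 25),
    cut_geometry=CutGeometry.STAGGERED,
    stagger_offsets=(18, 23),
)

PROFILES: dict[str, NucleaseProfile] = {"SpCas9": SPCAS9, "AsCas12a": ASCAS12A}


@dataclass(frozen=True)
class Guide:
    """A guide RNA spacer (DNA alphabet, uppercase ACGT)."""

    id: str
    spacer: str

    def __post_init__(self) -> None:
        validate_dna(self.spacer, what=f"guide {self.id!r} spacer")

    def validate_for(self, profile: NucleaseProfile) -> None:
        lo, hi = profile.spacer_len_range
        if not lo <= len(self.spacer) <= hi:
            raise ValueError(
                f"guide {self.id!r} spacer length {len(self.spacer)} outside "
                f"{profile.name} range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class TargetSite:
    """One protospacer placement on the plus strand of a reference."""

    reference_id: str
    strand: Strand
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    cut_window: tuple[int, int]  # inclusive gap-coordinate pair

    def __post_init__(self) -> None:
        if self.cut_window[0] > self.cut_window[1]:
            raise ValueError(f"cut_window reversed: {self.cut_window}")


def match_pam(sequence: str, pattern: str) -> bool:
    """True iff every base of ``sequence`` belongs to the corresponding IUPAC
    class of ``pattern``.  Lengths must agree."""
    if len(sequence) != len(pattern):
        raise ValueError(
            f"PAM length mismatch: sequence {len(sequence)} vs pattern {len(pattern)}"
        )
    return all(base in IUPAC_CLASSES[code] for base, code in zip(sequence, pattern))


def _pam_plus_interval(
    proto_start: int, proto_end: int, strand: Strand, profile: NucleaseProfile
) -> tuple[int, int]:
    """Plus-strand interval of the PAM adjacent to a protospacer placement."""
    plen = profile.pam_len
    # In protospacer orientation the PAM is 5' or 3' of the spacer; on the
    # minus strand those sides swap in plus-strand coordinates.
    pam_left = (profile.pam_side is PamSide.FIVE_PRIME) == (strand is Strand.PLUS)
    if pam_left:
        return proto_start - plen, proto_start
    return proto_end, proto_end + plen


def _cut_window(
    proto: tuple[int, int],
    pam_iv: tuple[int, int],
    profile: NucleaseProfile,
    reference_id: str,
) -> tuple[int, int]:
    s, e = proto
    if profile.cut_geometry is CutGeometry.BLUNT:
        offsets = [profile.blunt_offset]
    else:
        offsets = list(profile.stagger_offsets)
    # PAM-proximal protospacer end in plus-strand coordinates:
    pam_proximal_is_start = pam_iv[0] < s
    cuts = []
    for off in offsets:
        cut = s + off if pam_proximal_is_start else e - off
        if not 0 <= cut:
            raise ValueError(
                f"cut offset {off} maps to negative coordinate {cut} on "
                f"{reference_id}"
            )
        cuts.append(cut)
    return min(cuts), max(cuts)


def cut_positions(site: TargetSite, profile: NucleaseProfile) -> tuple[int, int]:
    """Predicted cut coordinates for a site, as an inclusive gap-coordinate
    pair on the plus strand.

    Blunt chemistry yields a width-0 window (both ends equal); staggered
    chemistry yields the two strand cuts mapped through the site's
    orientation.
    """
    return _cut_window(
        site.protospacer_interval, site.pam_interval, profile, site.reference_id
    )


def locate_target(
    guide: Guide,
    reference: str,
    profile: NucleaseProfile,
    reference_id: str = "ref",
) -> list[TargetSite]:
    """Every exact protospacer occurrence of ``guide`` on either strand of
    ``reference`` whose adjacent PAM satisfies the profile's pattern.

    Hits are ordered by ascending plus-strand protospacer start, plus strand
    before minus at ties.  N in the reference never matches a spacer base.
    """
    validate_dna(reference, allow_n=True, what="reference")
    guide.validate_for(profile)
    spacer = guide.spacer
    L = len(spacer)
    n = len(reference)
    hits: list[TargetSite] = []
    for strand, needle in ((Strand.PLUS, spacer), (Strand.MINUS, revcomp(spacer))):
        start = reference.find(needle)
        while start != -1:
            proto = (start, start + L)
            pam_iv = _pam_plus_interval(start, start + L, strand, profile)
            if 0 <= pam_iv[0] and pam_iv[1] <= n:
                pam_plus = reference[pam_iv[0] : pam_iv[1]]
                pam_seq = pam_plus if strand is Strand.PLUS else revcomp(pam_plus)
                if match_pam(pam_seq, profile.pam_pattern):
                    hits.append(
                        TargetSite(
                            reference_id=reference_id,
                            strand=strand,
                            protospacer_interval=proto,
                            pam_interval=pam_iv,
                            cut_window=_cut_window(proto, pam_iv, profile, reference_id),
                        )
                    )
            start = reference.find(needle, start + 1)
    hits.sort(key=lambda h: (h.protospacer_interval[0], h.strand is Strand.MINUS))
    return hits


def site_pam_sequence(site: TargetSite, reference: str) -> str:
    """PAM sequence of a site in protospacer orientation."""
    pam_plus = reference[site.pam_interval[0] : site.pam_interval[1]]
    return pam_plus if site.strand is Strand.PLUS else revcomp(pam_plus)


def sites_table(sites: list[TargetSite], reference: str) -> pd.DataFrame:
    """Site report with 1-based inclusive coordinates."""
    rows = []
    for s in sites:
        rows.append(
            {
                "reference_id": s.reference_id,
                "strand": s.strand.value,
                "protospacer_start_1based": s.protospacer_interval[0] + 1,
                "protospacer_end": s.protospacer_interval[1],
                "pam": site_pam_sequence(s, reference),
                "cut_window": f"{s.cut_window[0]}..{s.cut_window[1]}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "reference_id",
            "strand",
            "protospacer_start_1based",
            "protospacer_end",
            "pam",
            "cut_window",
        ],
    )
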