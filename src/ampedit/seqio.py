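"""Small sequence/IO helpers shared across the package.

FASTA and FASTQ parsing is delegated to Bio.SeqIO; gzipped FASTQ is
transparently supported by file extension.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(
            f"{what} contains invalid characters {sorted(bad)!r}; "
            f"expected uppercase {'ACGTN' if allow_n else 'ACGT'}"
        )
    return seq


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an ordered {id: uppercase sequence} dict."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")
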