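"""Microhomology enumeration and MMEJ deletion-product prediction.

Microhomology-mediated end joining (MMEJ) repairs a double-strand break by
annealing two short identical sequences (direct repeats) that flank the cut;
the repair deletes one repeat copy plus everything between the copies, so
each flanking repeat pair predicts one specific deletion allele.

:func:`enumerate_microhomologies` finds every maximal pair of identical
substrings straddling a cut window, :func:`predict_mmej_products` constructs
the deletion allele each pair implies, and :func:`junction_microhomology`
measures the repeat signature of an *observed* deletion (the number of
alternative placements of the same deletion product, i.e. how far the
deletion can be slid without changing the resulting sequence).

All coordinates are 0-based half-open; cut windows are inclusive gap-
coordinate pairs as produced by :mod:`ampedit.refmodel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_LEN = 2
DEFAULT_SEARCH_WINDOW = 30


@dataclass(frozen=True)
class MicrohomologyPair:
    """Two identical non-overlapping repeat copies flanking a cut."""

    left_copy: tuple[int, int]
    right_copy: tuple[int, int]
    mh_seq: str
    mh_len: int

    @property
    def deletion_len(self) -> int:
        return self.right_copy[0] - self.left_copy[0]


@dataclass(frozen=True)
class MmejProduct:
    """The deletion allele predicted by one microhomology pair."""

    pair: MicrohomologyPair
    deleted_interval: tuple[int, int]
    deletion_len: int
    product_seq: str
    frameshift: bool


def enumerate_microhomologies(
    reference: str,
    cut_window: tuple[int, int],
    search_window: int = DEFAULT_SEARCH_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[MicrohomologyPair]:
    """All maximal identical substring pairs straddling ``cut_window``.

    A pair consists of a left copy ending within ``search_window`` nt left of
    the cut window (and not beyond its right edge) and a right copy starting
    within ``search_window`` nt right of it (and not before its left edge);
    copies may abut the window but must not overlap each other.  Pairs are
    maximal under joint extension: extending both copies one base left or
    right breaks the identity.  Sorted by mh_len descending, then implied
    deletion length ascending, then left start.
    """
    n = len(reference)
    c0, c1 = cut_window
    if not (0 <= c0 <= c1 <= n):
        raise ValueError(f"cut_window {cut_window} outside reference of length {n}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if search_window < min_len:
        raise ValueError("search_window must be >= min_len")

    s = np.frombuffer(reference.encode(), dtype=np.uint8)
    # ext[i, j] = longest common extension of reference[i:] and reference[j:]
    ext = np.zeros((n + 1, n + 1), dtype=np.int32)
    eq = s[:, None] == s[None, :]
    for i in range(n - 1, -1, -1):
        ext[i, :n][eq[i]] = ext[i + 1, 1 : n + 1][eq[i]] + 1

    pairs: list[MicrohomologyPair] = []
    lo_j = max(c0, 0)
    hi_j = min(c1 + search_window + 1, n)
    for j in range(lo_j, hi_j):
        for i in range(j):
            L = int(ext[i, j])
            if L < min_len:
                continue
            # maximality on the left: copies not jointly extendable
            if i > 0 and reference[i - 1] == reference[j - 1]:
                continue
            l1 = i + L
            if not (c0 - search_window <= l1 <= c1):
                continue
            if j < l1:  # overlapping copies
                continue
            pairs.append(
                MicrohomologyPair(
                    left_copy=(i, l1),
                    right_copy=(j, j + L),
                    mh_seq=reference[i:l1],
                    mh_len=L,
                )
            )
    pairs.sort(key=lambda p: (-p.mh_len, p.deletion_len, p.left_copy[0]))
    return pairs


def predict_mmej_products(
    pairs: list[MicrohomologyPair], reference: str
) -> list[MmejProduct]:
    """Deletion allele for each pair: remove ``[left_copy.start,
    right_copy.start)``, keeping one repeat copy.  Products with identical
    sequence are deduplicated (first in input order wins)."""
    products: list[MmejProduct] = []
    seen: set[str] = set()
    for pair in pairs:
        d0 = pair.left_copy[0]
        d1 = pair.right_copy[0]
        product = reference[:d0] + reference[d1:]
        if product in seen:
            continue
        seen.add(product)
        dlen = d1 - d0
        products.append(
            MmejProduct(
                pair=pair,
                deleted_interval=(d0, d1),
                deletion_len=dlen,
                product_seq=product,
                frameshift=dlen % 3 != 0,
            )
        )
    return products


def junction_microhomology(
    reference: str, deletion: tuple[int, int]
) -> tuple[int, tuple[int, int]]:
    """Junction microhomology of an observed deletion.

    Returns ``(mh_len, ambiguity_interval)`` where ``mh_len`` is the number
    of alternative placements of the deletion yielding the same product
    (left-shifts plus right-shifts) and ``ambiguity_interval`` is the
    inclusive gap-coordinate range the deletion's left edge can occupy.
    ``mh_len == 0`` means the junction carries no repeat signature (a clean
    blunt join).
    """
    d0, d1 = deletion
    n = len(reference)
    if not (0 <= d0 < d1 <= n):
        raise ValueError(f"deletion {deletion} out of bounds for length-{n} reference")
    right = 0
    while d1 + right < n and reference[d0 + right] == reference[d1 + right]:
        right += 1
    left = 0
    while d0 - left - 1 >= 0 and reference[d0 - left - 1] == reference[d1 - left - 1]:
        left += 1
    return left + right, (d0 - left, d0 + right)


def microhomology_table(pairs: list[MicrohomologyPair]) -> pd.DataFrame:
    """MH report with 1-based start coordinates, one row per pair."""
    rows = [
        {
            "mh_seq": p.mh_seq,
            "mh_len": p.mh_len,
            "left_start_1based": p.left_copy[0] + 1,
            "right_start_1based": p.right_copy[0] + 1,
            "deletion_len": p.deletion_len,
            "frameshift": p.deletion_len % 3 != 0,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mh_seq",
            "mh_len",
            "left_start_1based",
            "right_start_1based",
            "deletion_len",
            "frameshift",
        ],
    )
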