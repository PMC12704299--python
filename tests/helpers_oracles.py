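"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (plain string
scanning, exhaustive recursion) and shares no code with the package's own
algorithms.
"""

from functools import lru_cache

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def align_score_bruteforce(a: str, b: str, match=2.0, mismatch=-2.0,
                           gap_open=-6.0, gap_extend=-1.0) -> float:
    """Optimal global affine-gap score by exhaustive memoized recursion.

    The opening penalty is charged on the first gapped base; extending an
    already-open gap in the same sequence costs gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if i < len(a):  # a[i] against a gap in b
            cost = gap_extend if state == "A" else gap_open
            options.append(cost + best(i + 1, j, "A"))
        if j < len(b):  # b[j] against a gap in a
            cost = gap_extend if state == "B" else gap_open
            options.append(cost + best(i, j + 1, "B"))
        return max(options)

    result = best(0, 0, "M")
    best.cache_clear()
    return result


def locate_oracle(spacer: str, reference: str, pam_pattern: str,
                  pam_five_prime: bool) -> list[tuple[str, int, int]]:
    """Every exact protospacer+PAM placement, as (strand, start, end) on the
    plus strand, by per-position scanning."""
    hits = []
    L, P = len(spacer), len(pam_pattern)

    def pam_ok(seq: str) -> bool:
        return len(seq) == P and all(s in IUPAC[p] for s, p in zip(seq, pam_pattern))

    n = len(reference)
    for start in range(n - L + 1):
        window = reference[start:start + L]
        # plus strand
        if window == spacer:
            pam = (reference[start - P:start] if pam_five_prime
                   else reference[start + L:start + L + P])
            lo_ok = start - P >= 0 if pam_five_prime else start + L + P <= n
            if lo_ok and pam_ok(pam):
                hits.append(("+", start, start + L))
        # minus strand: protospacer read on the reverse complement
        if rc(window) == spacer:
            if pam_five_prime:
                plus_iv = reference[start + L:start + L + P]
                ok = start + L + P <= n
            else:
                plus_iv = reference[start - P:start]
                ok = start - P >= 0
            if ok and pam_ok(rc(plus_iv)):
                hits.append(("-", start, start + L))
    return sorted(hits, key=lambda h: (h[1], h[0] == "-"))


def mh_oracle(reference: str, cut_window, search_window: int, min_len: int):
    """All maximal identical substring pairs straddling the cut, by direct
    definition: anchor at every (i, j), extend while identical, filter."""
    n = len(reference)
    c0, c1 = cut_window
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if reference[i] != reference[j]:
                continue
            if i > 0 and reference[i - 1] == reference[j - 1]:
                continue  # not the left edge of a maximal pair
            L = 0
            while j + L < n and reference[i + L] == reference[j + L]:
                L += 1
            if L < min_len:
                continue
            l1 = i + L
            if not (c0 - search_window <= l1 <= c1):
                continue
            if not (c0 <= j <= c1 + search_window):
                continue
            if j < l1:
                continue
            pairs.add((i, l1, j, j + L))
    return pairs


def offtarget_oracle(spacer: str, database: dict, pam_pattern: str,
                     pam_five_prime: bool, max_mm: int):
    """Per-position Hamming scan; N in the database matches nothing,
    including in the PAM."""
    P = len(pam_pattern)
    L = len(spacer)

    def pam_ok(seq: str) -> bool:
        return len(seq) == P and all(
            s != "N" and s in IUPAC[p] for s, p in zip(seq, pam_pattern)
        )

    hits = set()
    for seq_id, seq in database.items():
        n = len(seq)
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else rc(seq)
            for s in range(n - L + 1):
                window = oriented[s:s + L]
                mm = sum(a != b for a, b in zip(window, spacer))
                if mm > max_mm:
                    continue
                pam = (oriented[s - P:s] if pam_five_prime
                       else oriented[s + L:s + L + P])
                bounds = s - P >= 0 if pam_five_prime else s + L + P <= n
                if not bounds or not pam_ok(pam):
                    continue
                if strand == "+":
                    iv = (s, s + L)
                else:
                    iv = (n - s - L, n - s)
                hits.add((seq_id, strand, iv[0], iv[1], mm))
    return hits
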