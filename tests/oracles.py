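"""Independent brute-force oracles shared across test modules.

Each oracle recomputes a quantity by a method structurally different
from the implementation it checks (exhaustive substring scan, exhaustive
draw enumeration, position-set intersection)."""

from itertools import combinations

STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def brute_force_runs(sequence: str, min_run_length: int):
    """All maximal homopolymer runs by testing every substring for
    homogeneity and keeping the maximal ones (quadratic)."""
    L = len(sequence)
    out = []
    for i in range(L):
        for j in range(i + min_run_length, L + 1):
            ch = sequence[i]
            if ch not in STANDARD:
                continue
            if sequence[i:j] != ch * (j - i):
                continue
            left_ok = i == 0 or sequence[i - 1] != ch
            right_ok = j == L or sequence[j] != ch
            if left_ok and right_ok:
                out.append((ch, i + 1, j))
    return sorted(out, key=lambda r: r[1])


def enumerate_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every C(N, n) draw (N <= 12)."""
    items = list(range(N))
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(items, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def interval_overlap_by_sets(a_start, a_end, b_start, b_end) -> int:
    """Shared positions via explicit position-set intersection."""
    return len(set(range(a_start, a_end + 1)) & set(range(b_start, b_end + 1)))
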