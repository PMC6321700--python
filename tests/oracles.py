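"""Independent brute-force oracles used to validate the implementations.

These deliberately re-derive results from first principles (path
enumeration, mutant enumeration, candidate scanning) and share no code
with the package internals. Translation in the NG86 oracle goes through
Biopython rather than the package's codon table.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Seq import Seq


def sw_oracle_score(a: str, b: str, submat, alphabet: str, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score by enumerating alignment-path
    extensions (memoised recursion over (position, previous-op) states).

    Gap cost convention: a gap of length L costs gap_open + L*gap_extend.
    """
    ai = [alphabet.index(c) for c in a]
    bi = [alphabet.index(c) for c in b]
    n, m = len(ai), len(bi)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, prev: str) -> int:
        # best additional score of any path continuing from (i, j);
        # ending the local alignment here is always allowed (score 0)
        best = 0
        if i < n and j < m:
            best = max(best, int(submat[ai[i], bi[j]]) + ext(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if prev == "U" else gap_open + gap_extend
            best = max(best, -cost + ext(i + 1, j, "U"))
        if j < m:
            cost = gap_extend if prev == "L" else gap_open + gap_extend
            best = max(best, -cost + ext(i, j + 1, "L"))
        return best

    return max(ext(i, j, "S") for i in range(n + 1) for j in range(m + 1))


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Fractional site counts by enumerating all 9 single-base mutants."""
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mut) == _aa(codon) and _aa(mut) != "*":
                s += 1 / 3
    return s, 3.0 - s


def ng86_diffs_oracle(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged difference counts by enumerating all orders of
    the differing positions; stop-visiting pathways skipped
    (renormalised), falling back to all pathways when all are blocked."""
    pos = [p for p in range(3) if ca[p] != cb[p]]
    if not pos:
        return 0.0, 0.0

    def path_counts(order, allow_stop):
        cur, sd, nd = ca, 0.0, 0.0
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if _aa(nxt) == "*" and not allow_stop:
                return None
            if _aa(nxt) == _aa(cur) and _aa(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [path_counts(o, False) for o in permutations(pos)]
    ok = [r for r in results if r is not None]
    if not ok:
        ok = [path_counts(o, True) for o in permutations(pos)]
    return (
        sum(r[0] for r in ok) / len(ok),
        sum(r[1] for r in ok) / len(ok),
    )


def n50_oracle(lengths) -> int:
    """N50 by testing every observed length as a candidate."""
    total = sum(lengths)
    candidates = [
        L for L in sorted(set(lengths), reverse=True)
        if sum(x for x in lengths if x >= L) * 2 >= total
    ]
    return max(candidates)
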