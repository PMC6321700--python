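"""Codon-aware alignment and Nei-Gojobori (1986) Ka/Ks estimation.

The molecular-evolution leg of the pipeline asks whether recovered
"missing" genes evolve under different selective pressure than the
genome-wide background. For an ortholog pair this module

1. aligns the two peptides globally (Needleman-Wunsch, affine gaps) and
   back-translates the peptide alignment to a codon alignment, and
2. estimates Ka (nonsynonymous rate) and Ks (synonymous rate) by the
   NG86 counting method: fractional synonymous/nonsynonymous site
   counts per codon, pathway-averaged difference counts, and the
   Jukes-Cantor correction d = -(3/4)·ln(1 - (4/3)p).

Conventions (stated so every worked example is reproducible):
mutations that create a stop codon count as nonsynonymous when counting
sites; mutational pathways passing through a stop codon are skipped and
the average is renormalised over the remaining pathways (if every
pathway is blocked, all pathways are used and stop transitions count as
nonsynonymous). Gapped codon columns and columns containing a stop
codon are excluded entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _align
from .homology import ScoringScheme, _matrix, encode_peptide
from .seqio_qc import _CODON_TABLE, translate

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "GroupComparison",
    "codon_align",
    "ng86_sites",
    "ng86_diffs",
    "ng86_kaks",
    "kaks_pair",
    "compare_groups",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CodonAlignment:
    """A frame-preserving pairwise CDS alignment (gap runs of length 3k)."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a) // 3

    def codon_columns(self):
        for k in range(self.n_columns):
            yield self.aligned_a[3 * k : 3 * k + 3], self.aligned_b[3 * k : 3 * k + 3]


def codon_align(
    cds_a: str,
    cds_b: str,
    scheme: ScoringScheme | None = None,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Globally align two CDS at the codon level.

    The peptides are aligned with Needleman-Wunsch and each peptide
    column is expanded back to its source codon (or a ``---`` gap), so
    stripping gaps recovers the inputs byte-for-byte. Terminal stop
    codons are allowed (the terminator aligns like any residue);
    internal stops raise.
    """
    scheme = scheme or ScoringScheme()
    cds_a = str(cds_a).upper().replace("U", "T")
    cds_b = str(cds_b).upper().replace("U", "T")
    pep_a = translate(cds_a, strict=True)
    pep_b = translate(cds_b, strict=True)
    _, sub = _matrix(scheme.matrix_name)
    ea = encode_peptide(pep_a, scheme)
    eb = encode_peptide(pep_b, scheme)
    _, qa, sa = _align.global_align(ea, eb, sub, scheme.gap_open, scheme.gap_extend)
    out_a, out_b = [], []
    for ia, ib in zip(qa, sa):
        out_a.append(cds_a[3 * ia : 3 * ia + 3] if ia >= 0 else "---")
        out_b.append(cds_b[3 * ib : 3 * ib + 3] if ib >= 0 else "---")
    return CodonAlignment(id_a=id_a, id_b=id_b, aligned_a="".join(out_a), aligned_b="".join(out_b))


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each of the three positions contributes the fraction of its three
    single-nucleotide changes that are synonymous; changes to stop
    codons count as nonsynonymous. The two fractions sum to 3 exactly.
    """
    codon = codon.upper()
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        raise ValueError(f"not a valid codon: {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no NG86 site decomposition")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[mutant] == aa:  # stop != aa, so stops are nonsyn
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    For codons differing at k positions, all k! orderings of the single
    changes are enumerated; each step is classified by whether it
    preserves the amino acid. Pathways visiting a stop codon are
    skipped and the average renormalised; if every pathway is blocked,
    all pathways are used with stop transitions counted nonsynonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if _CODON_TABLE.get(c) in (None, "*"):
            raise ValueError(f"invalid or stop codon: {c!r}")
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = codon_a
        sd = nd = 0.0
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            if _CODON_TABLE[nxt] == "*" and not allow_stops:
                return None
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur] and _CODON_TABLE[nxt] != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order, False) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff_pos)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined for p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class KaKsResult:
    """NG86 counts and rates for one ortholog pair.

    ``ka``/``ks``/``ratio`` are None when undefined (Jukes-Cantor
    domain violation, or Ks = 0 for the ratio); ``status`` says why.
    """

    id_a: str
    id_b: str
    n_codons: int  # ungapped, stop-free codon columns counted
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ka: float | None
    ks: float | None
    ratio: float | None
    status: str = "ok"


def ng86_kaks(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks over a codon alignment.

    Site counts are averaged over the two sequences across ungapped,
    stop-free codon columns; differences are pathway-averaged per
    column; both proportions get the Jukes-Cantor correction.
    """
    S_a = S_b = Sd = Nd = 0.0
    n_cols = 0
    for ca, cb in alignment.codon_columns():
        if "-" in ca or "-" in cb:
            continue
        if _CODON_TABLE.get(ca) == "*" or _CODON_TABLE.get(cb) == "*":
            continue
        sa, _ = ng86_sites(ca)
        sb, _ = ng86_sites(cb)
        S_a += sa
        S_b += sb
        sd, nd = ng86_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n_cols += 1
    if n_cols == 0:
        raise ValueError("no comparable (ungapped, stop-free) codon columns")
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_cols - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(pS)
    ka = _jukes_cantor(pN)
    status = "ok"
    ratio = None
    if ka is None or ks is None:
        status = "undefined: proportion >= 3/4 (Jukes-Cantor domain)"
    elif ks == 0.0:
        status = "undefined: Ks = 0" if ka == 0.0 else "undefined: Ks = 0, Ka > 0"
    else:
        ratio = ka / ks
    return KaKsResult(
        id_a=alignment.id_a, id_b=alignment.id_b, n_codons=n_cols,
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, ka=ka, ks=ks, ratio=ratio,
        status=status,
    )


def kaks_pair(
    cds_a: str, cds_b: str, scheme: ScoringScheme | None = None,
    id_a: str = "a", id_b: str = "b",
) -> KaKsResult:
    """Convenience: codon-align two CDS and run NG86."""
    return ng86_kaks(codon_align(cds_a, cds_b, scheme, id_a=id_a, id_b=id_b))


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    n_excluded_a: int
    n_excluded_b: int
    t_statistic: float
    p_value: float


def compare_groups(values_a: Iterable, values_b: Iterable) -> GroupComparison:
    """Welch two-sided t-test of two Ka/Ks groups.

    Undefined ratios (None/NaN) are excluded, with counts reported.
    """
    def clean(vals):
        arr = [v for v in vals if v is not None and math.isfinite(v)]
        return arr

    raw_a, raw_b = list(values_a), list(values_b)
    a, b = clean(raw_a), clean(raw_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite Ka/Ks values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        n_a=len(a), n_b=len(b),
        n_excluded_a=len(raw_a) - len(a), n_excluded_b=len(raw_b) - len(b),
        t_statistic=float(t), p_value=float(p),
    )
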