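"""Translated homology search: local alignment best hits with identity
and E-value filters.

This is the desk-scale stand-in for a BLASTP best-hit screen: optimal
Smith-Waterman alignment with affine gaps (no word-seeding heuristics),
a Karlin-Altschul E-value model ``E = K·m·n·exp(-lambda·S)``, and the
recovery filters identity > 40% and E <= 1e-10. The identity
denominator is the number of aligned columns including gap columns
(gaps count as non-identical), a deliberately conservative choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _align

__all__ = ["ScoringScheme", "AlignmentResult", "align_local", "evalue", "search_best_hit"]


@dataclass(frozen=True)
class ScoringScheme:
    """Protein scoring parameters (BLAST-like defaults).

    A gap of length L costs ``gap_open + L * gap_extend``. ``lam`` and
    ``karlin_k`` are the Karlin-Altschul parameters of the E-value
    model; the ungapped BLOSUM62 constants are applied to gapped scores,
    which preserves threshold behaviour without reproducing BLAST's
    exact statistics.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.lam <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be > 0")


@lru_cache(maxsize=4)
def _matrix(name: str) -> tuple[str, np.ndarray]:
    m = substitution_matrices.load(name)
    alphabet = str(m.alphabet)
    arr = np.asarray(m, dtype=np.int64)
    return alphabet, arr


def encode_peptide(peptide: str, scheme: ScoringScheme) -> np.ndarray:
    """Map residues to substitution-matrix indices; invalid residues raise."""
    alphabet, _ = _matrix(scheme.matrix_name)
    lut = {ch: i for i, ch in enumerate(alphabet)}
    try:
        return np.array([lut[ch] for ch in str(peptide).upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"residue {exc.args[0]!r} not in {scheme.matrix_name} alphabet"
        ) from None


@dataclass(frozen=True)
class AlignmentResult:
    """A scored local alignment between a query and a subject peptide."""

    query_id: str
    subject_id: str
    score: int
    identity: float  # % identical positions over aligned columns (gaps included)
    aligned_length: int
    query_coverage: float
    e_value: float
    query_aligned: str
    subject_aligned: str
    query_start: int = 0  # 0-based, on the query
    subject_start: int = 0


def _result_from_path(
    query: str, subject: str, qa: np.ndarray, sa: np.ndarray, score: int,
    e_value: float, query_id: str, subject_id: str,
) -> AlignmentResult:
    q_chars, s_chars = [], []
    matches = 0
    for qi, si in zip(qa, sa):
        qc = query[qi] if qi >= 0 else "-"
        sc = subject[si] if si >= 0 else "-"
        if qc != "-" and qc == sc:
            matches += 1
        q_chars.append(qc)
        s_chars.append(sc)
    ncol = len(q_chars)
    n_q_res = int((qa >= 0).sum())
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        identity=100.0 * matches / ncol if ncol else 0.0,
        aligned_length=ncol,
        query_coverage=n_q_res / len(query) if query else 0.0,
        e_value=e_value,
        query_aligned="".join(q_chars),
        subject_aligned="".join(s_chars),
        query_start=int(qa[qa >= 0][0]) if n_q_res else 0,
        subject_start=int(sa[sa >= 0][0]) if (sa >= 0).any() else 0,
    )


def align_local(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    database_length: int | None = None,
) -> AlignmentResult:
    """Optimal Smith-Waterman alignment of two peptides.

    Traceback ties are broken diagonal-first, then up, then left.
    ``database_length`` (for the E-value) defaults to the subject
    length; a search over a set passes the total residue count.
    """
    scheme = scheme or ScoringScheme()
    if not query or not subject:
        raise ValueError("peptides must be non-empty")
    _, sub = _matrix(scheme.matrix_name)
    a = encode_peptide(query, scheme)
    b = encode_peptide(subject, scheme)
    score, qa, sa = _align.local_align(a, b, sub, scheme.gap_open, scheme.gap_extend)
    n_db = database_length if database_length is not None else len(subject)
    ev = evalue(score, len(query), n_db, scheme)
    return _result_from_path(query.upper(), subject.upper(), qa, sa, score, ev, query_id, subject_id)


def evalue(
    score: float, query_length: int, database_length: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin-Altschul expected chance hits: E = K·m·n·exp(-lambda·S)."""
    scheme = scheme or ScoringScheme()
    if query_length <= 0 or database_length <= 0:
        raise ValueError("lengths must be positive")
    return scheme.karlin_k * query_length * database_length * math.exp(-scheme.lam * score)


def search_best_hit(
    reference,
    peptides: Iterable,
    min_identity: float = 40.0,
    max_e: float = 1e-10,
    scheme: ScoringScheme | None = None,
) -> AlignmentResult | None:
    """Best hit of a reference protein against a species peptide set.

    ``reference`` is ``(id, sequence)`` or a plain sequence; ``peptides``
    yields ``(id, sequence)`` pairs or SeqRecord-like objects. Among
    alignments with identity strictly above ``min_identity`` and E-value
    at most ``max_e``, the highest score wins; ties break by higher
    identity, longer alignment, then lexicographically smaller subject
    id. Returns None when nothing passes (order-invariant).
    """
    scheme = scheme or ScoringScheme()
    if isinstance(reference, (tuple, list)):
        query_id, query = reference
    else:
        query_id = getattr(reference, "id", "query")
        query = str(getattr(reference, "seq", reference))
    subjects = []
    for p in peptides:
        if isinstance(p, (tuple, list)):
            subjects.append((str(p[0]), str(p[1])))
        else:
            subjects.append((str(p.id), str(getattr(p, "seq", p))))
    if not subjects:
        warnings.warn(f"empty peptide set for query {query_id!r}; no hit possible")
        return None
    db_len = sum(len(s) for _, s in subjects)
    best = None
    best_key = None
    for sid, pep in subjects:
        r = align_local(
            query, pep, scheme, query_id=str(query_id), subject_id=sid,
            database_length=db_len,
        )
        if r.identity <= min_identity or r.e_value > max_e:
            continue
        key = (-r.score, -r.identity, -r.aligned_length, r.subject_id)
        if best_key is None or key < best_key:
            best, best_key = r, key
    return best
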