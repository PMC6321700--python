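"""Sequence I/O, read filtering, ORF extraction and redundancy collapse.

This module covers the pre-analysis steps of the missing-gene recovery
pipeline: FASTA/FASTQ round-tripping, the whole-read quality filter
(reads shorter than 70 bp, or with more than 5% of bases below Q30, are
dropped), longest-ORF extraction from assembled transcripts, and greedy
redundancy collapse of near-identical transcripts (CD-HIT-style
``-c 0.95 -aS 0.8`` semantics, computed with exact alignment instead of
word heuristics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SeqFormatError",
    "ReadFilterConfig",
    "TranscriptRecord",
    "AssemblyStats",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "filter_reads",
    "find_longest_orf",
    "translate",
    "collapse_redundancy",
    "assembly_stats",
]

# IUPAC alphabets (upper case; validation is case-insensitive)
NUCLEOTIDE_ALPHABET = set("ACGTURYSWKMBDHVN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class SeqFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


def _validate_alphabet(records: Sequence[SeqRecord], alphabet: str | None, path) -> None:
    if alphabet is None:
        return
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    for i, rec in enumerate(records):
        bad = set(str(rec.seq).upper()) - allowed
        if bad:
            raise SeqFormatError(
                f"{path}: record {i + 1} ({rec.id!r}) contains characters "
                f"{sorted(bad)} outside the {alphabet} alphabet"
            )


def read_fasta(path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords.

    ``alphabet`` may be ``"nucleotide"`` or ``"protein"`` to validate
    sequence characters against the corresponding IUPAC set. An empty
    file yields an empty list. A structurally malformed file raises
    :class:`SeqFormatError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise SeqFormatError(
                        f"{path}: line {lineno}: expected FASTA header '>' "
                        f"but found {line.strip()[:30]!r}"
                    )
                break
    records = list(SeqIO.parse(path, "fasta"))
    _validate_alphabet(records, alphabet, path)
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> int:
    """Write SeqRecords as FASTA (wrapped at ``width`` columns)."""
    records = list(records)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description or rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
    return len(records)


def read_fastq(path) -> list[SeqRecord]:
    """Read Phred+33 FASTQ. Quality/sequence length mismatches raise."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(path, "fastq"))
    except ValueError as exc:
        raise SeqFormatError(f"{path}: malformed FASTQ: {exc}") from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    records = list(records)
    SeqIO.write(records, path, "fastq")
    return len(records)


@dataclass(frozen=True)
class ReadFilterConfig:
    """Whole-read quality filter.

    Defaults mirror the pipeline's pre-assembly rule: drop reads shorter
    than 70 bp and reads in which more than 5% of bases fall below Q30.
    """

    min_length: int = 70
    quality_threshold: int = 30
    max_low_quality_fraction: float = 0.05

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (0 <= self.quality_threshold <= 93):
            raise ValueError("quality_threshold must be in [0, 93]")
        if not (0.0 <= self.max_low_quality_fraction <= 1.0):
            raise ValueError("max_low_quality_fraction must be in [0, 1]")


def filter_reads(
    reads: Iterable[SeqRecord], config: ReadFilterConfig | None = None
) -> tuple[list[SeqRecord], list[dict]]:
    """Apply the whole-read filter; return (kept reads, per-read log).

    A read is kept iff ``len >= min_length`` and the fraction of bases
    with Phred quality below ``quality_threshold`` is at most
    ``max_low_quality_fraction``. The log has one row per read with
    ``read_id``, ``verdict`` (kept/rejected) and ``reason``.
    """
    config = config or ReadFilterConfig()
    kept: list[SeqRecord] = []
    log: list[dict] = []
    for rec in reads:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise SeqFormatError(f"read {rec.id!r} has no quality values")
        if len(rec.seq) < config.min_length:
            log.append({"read_id": rec.id, "verdict": "rejected", "reason": "length"})
            continue
        n_low = sum(1 for q in quals if q < config.quality_threshold)
        if n_low / len(quals) > config.max_low_quality_fraction:
            log.append({"read_id": rec.id, "verdict": "rejected", "reason": "quality"})
            continue
        kept.append(rec)
        log.append({"read_id": rec.id, "verdict": "kept", "reason": ""})
    return kept, log


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(cds: str, strict: bool = True) -> str:
    """Translate a CDS with the standard genetic code.

    The terminator is rendered as ``*`` and permitted only as the final
    codon; an internal stop raises in strict mode. Codons containing
    non-ACGT characters translate to ``X``.
    """
    cds = str(cds).upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    pep = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*" and strict and i < n_codons - 1:
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        pep.append(aa)
    return "".join(pep)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with its extracted ORF.

    ``orf_start``/``orf_end`` are 0-based half-open coordinates on the
    reported strand (the stop codon, when present, is inside the span);
    ``peptide`` excludes the terminator.
    """

    id: str
    sequence: str
    orf_start: int
    orf_end: int
    strand: str
    peptide: str

    def __post_init__(self):
        if (self.orf_end - self.orf_start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")

    @property
    def orf_sequence(self) -> str:
        seq = self.sequence if self.strand == "+" else str(Seq(self.sequence).reverse_complement())
        return seq[self.orf_start : self.orf_end]


def _frame_orfs(seq: str, frame: int, require_start: bool):
    """Yield (start, end) nt spans of candidate ORFs in one frame.

    With ``require_start`` each span runs from an ATG to the first
    in-frame stop (stop included). Without it, spans are maximal
    stop-free codon runs (truncated at the sequence ends), again with a
    terminating stop included when one exists.
    """
    n = len(seq)
    codon_starts = range(frame, n - 2, 3)
    run_start = None
    for pos in codon_starts:
        codon = seq[pos : pos + 3]
        if codon in _STOP_CODONS:
            if run_start is not None:
                yield run_start, pos + 3
                run_start = None
            elif not require_start:
                # empty stop-to-stop span: nothing to emit
                pass
            continue
        if run_start is None:
            if require_start:
                if codon == "ATG":
                    run_start = pos
            else:
                run_start = pos
    if run_start is not None and not require_start:
        # truncated at the sequence end (trim to whole codons)
        end = run_start + 3 * ((n - run_start) // 3)
        if end > run_start:
            yield run_start, end


def find_longest_orf(
    sequence: str,
    min_length_aa: int = 100,
    require_start: bool = True,
    transcript_id: str = "transcript",
) -> TranscriptRecord | None:
    """Scan all six frames and return the longest ORF, or None.

    Ties are broken in favour of the + strand, then the smaller start
    coordinate. ``min_length_aa`` is the minimum peptide length
    (terminator excluded). With ``require_start`` on, only complete
    ATG-to-stop ORFs qualify; off, truncated stop-free spans at either
    sequence end are also considered.
    """
    seq = str(sequence).upper().replace("U", "T")
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in transcript: {sorted(bad)}")
    # Candidates are ranked by nt span (the stop codon is part of the
    # ORF), with complete stop-terminated ORFs preferred over truncated
    # runs of equal span, then by peptide; this ordering is invariant
    # under reverse-complementing the input (both scans see the same six
    # frames). + strand and smaller start break residual ties between
    # identical peptides.
    best = None
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            for start, end in _frame_orfs(s, frame, require_start):
                pep = translate(s[start:end], strict=True)
                complete = pep.endswith("*")
                if complete:
                    pep = pep[:-1]
                key = (-(end - start), 0 if complete else 1, pep,
                       0 if strand == "+" else 1, start)
                if best is None or key < best[0]:
                    best = (key, strand, start, end, pep)
    if best is None:
        return None
    _, strand, start, end, pep = best
    if len(pep) < min_length_aa:
        return None
    return TranscriptRecord(
        id=transcript_id, sequence=seq, orf_start=start, orf_end=end,
        strand=strand, peptide=pep,
    )


def collapse_redundancy(
    transcripts: Sequence[SeqRecord],
    identity_threshold: float = 0.95,
    min_coverage_shorter: float = 0.8,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Greedy redundancy collapse over transcripts sorted by length.

    Each transcript joins the first existing cluster whose (longer)
    representative contains an infix match of the full transcript at
    identity >= ``identity_threshold``; otherwise it founds a new
    cluster. Because the whole shorter sequence is aligned, coverage of
    the shorter sequence is 1.0, which satisfies any
    ``min_coverage_shorter`` <= 1. Returns (representatives, member ->
    representative map); representatives keep descending-length order.
    """
    if not transcripts:
        raise ValueError("collapse_redundancy requires at least one transcript")
    order = sorted(transcripts, key=lambda r: (-len(r.seq), r.id))
    reps: list[SeqRecord] = []
    cluster_map: dict[str, str] = {}
    for rec in order:
        seq = str(rec.seq).upper()
        placed = False
        for rep in reps:
            rep_seq = str(rep.seq).upper()
            max_dist = int(len(seq) * (1.0 - identity_threshold))
            res = edlib.align(seq, rep_seq, mode="HW", task="distance", k=max_dist)
            d = res["editDistance"]
            if d < 0:
                continue
            identity = (len(seq) - d) / len(seq)
            if identity >= identity_threshold:
                cluster_map[rec.id] = rep.id
                placed = True
                break
        if not placed:
            reps.append(rec)
            cluster_map[rec.id] = rec.id
    return reps, cluster_map


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bp: int
    n50: int
    mean_length: float


def assembly_stats(sequences: Sequence) -> AssemblyStats:
    """Basic assembly summary; N50 via the cumulative-sum definition."""
    lengths = sorted((len(getattr(s, "seq", s)) for s in sequences), reverse=True)
    if not lengths:
        raise ValueError("assembly_stats requires at least one sequence")
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if cum * 2 >= total:
            n50 = length
            break
    return AssemblyStats(
        n_sequences=len(lengths), total_bp=total, n50=n50,
        mean_length=total / len(lengths),
    )
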