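"""Synthetic study-system generator with known ground truth.

The real study rests on ~200 avian RNA-seq libraries that cannot be
re-assembled at desk scale, so every pipeline stage is exercised
against a generator that emulates the study conditions with known
truth:

* a candidate "missing" reference gene set (CDS + protein), with
  per-gene GC targets drawn from a two-component mixture (the bimodal
  GC distribution seen in avian missing genes);
* per-(gene, species) status — ``annotated`` (present, in the mock
  annotation), ``hidden`` (present in transcripts but unannotated, the
  recoverable class) or ``lost`` (truly absent: no transcripts);
* codon-level divergence of each present ortholog via a
  proposal/acceptance substitution process with target Ka/Ks ratio
  omega — synonymous proposals are accepted with probability 1 and
  nonsynonymous ones with probability min(omega, 1) (for omega > 1 the
  weights become 1/omega and 1), changes creating stop codons are
  rejected, so the realised ratio is auditable by counting acceptances;
* fragmented transcripts (for OHR < 1), optional UTR-like flanks,
  strand flips and near-duplicates;
* gene x tissue counts whose noise-free profile hits a per-gene target
  tissue-specificity index exactly;
* FASTQ reads with labelled too-short / low-quality fractions.

All randomness flows from one seed through named per-stage substreams,
so identical (config, seed) gives byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqio_qc import _CODON_TABLE, translate, write_fasta, write_fastq

__all__ = [
    "GCMixture",
    "LengthDist",
    "FragmentationConfig",
    "ReadSimConfig",
    "SimulationConfig",
    "SimulationError",
    "ReferenceSet",
    "OrthologSet",
    "TranscriptSet",
    "SimulationResult",
    "tsi_profile",
    "simulate_reference_geneset",
    "evolve_species_orthologs",
    "fragment_transcripts",
    "simulate_expression",
    "simulate_reads",
    "simulate_all",
    "write_outputs",
]

_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
_STOPS = ("TAA", "TAG", "TGA")
_CODON_GC = np.array([sum(1 for b in c if b in "GC") for c in _SENSE_CODONS], float)
_STOP_GC = np.array([sum(1 for b in c if b in "GC") for c in _STOPS], float)

#: named substreams: all stage randomness derives from (stage id, seed)
_STAGES = {"reference": 11, "status": 23, "evolve": 37, "fragment": 53, "expression": 71, "reads": 89}

_DEFAULT_SPECIES = ("chicken", "duck", "pigeon", "goose", "zebra_finch")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GCMixture:
    """Two-component normal mixture for per-gene GC targets (percent).

    Defaults emulate the bimodal GC distribution of avian missing
    genes: a minor component around the genomic background and a major
    GC-rich component.
    """

    means: tuple[float, float] = (46.0, 60.0)
    sds: tuple[float, float] = (3.0, 5.0)
    weights: tuple[float, float] = (0.35, 0.65)

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("mixture sds must be > 0")


@dataclass(frozen=True)
class LengthDist:
    """CDS length distribution in codons (gamma, clipped to [min, max])."""

    min_codons: int = 100
    max_codons: int = 500
    mean_codons: float = 220.0

    def __post_init__(self):
        if self.min_codons < 10:
            raise ValueError("CDS length must be >= 10 codons")
        if not (self.min_codons <= self.mean_codons <= self.max_codons):
            raise ValueError("mean length must lie within [min, max]")


@dataclass(frozen=True)
class FragmentationConfig:
    """Transcript fragmentation / decoration settings.

    With ``full_length_prob = 1`` every transcript carries the whole
    CDS (coverage 1.0); lower values draw coverage uniformly from
    [min_coverage, 1] for the remainder.
    """

    full_length_prob: float = 1.0
    min_coverage: float = 0.4
    utr_prob: float = 0.3
    utr_length: tuple[int, int] = (20, 150)
    utr_gc: float = 45.0
    revcomp_prob: float = 0.3
    duplicate_prob: float = 0.1
    max_duplicate_trim: float = 0.1

    def __post_init__(self):
        for p in (self.full_length_prob, self.utr_prob, self.revcomp_prob, self.duplicate_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("fragmentation probabilities must be in [0, 1]")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read simulation: labelled fractions exercise the QC filter."""

    n_reads: int = 1000
    read_length: int = 150
    frac_short: float = 0.1
    frac_low_quality: float = 0.1
    base_quality: int = 40
    low_quality: int = 20
    low_quality_fraction_of_bases: float = 0.10

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.frac_short + self.frac_low_quality > 1.0:
            raise ValueError("flagged fractions must sum to <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full synthetic run."""

    n_genes: int = 100
    n_species: int = 5
    species: tuple[str, ...] | None = None
    p_hidden: float = 0.3  # P(absent from mock annotation | present)
    p_lost: float = 0.1  # P(truly lost in a species)
    omega: float | Sequence[float] = 0.5
    divergence: float = 0.3  # expected accepted substitutions per evolvable nt site
    gc_mixture: GCMixture = field(default_factory=GCMixture)
    length_dist: LengthDist = field(default_factory=LengthDist)
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    n_tissues: int = 12
    tsi_targets: Sequence[float] | None = None
    library_sizes: float | Sequence[float] = 1_000_000.0
    dispersion: float = 0.05
    reads: ReadSimConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_species < 1:
            raise ValueError("n_genes and n_species must be >= 1")
        for p in (self.p_hidden, self.p_lost):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        om = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if (om <= 0).any():
            raise ValueError("omega must be > 0")
        if om.size not in (1, self.n_genes):
            raise ValueError("omega must be scalar or one value per gene")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.tsi_targets is not None:
            t = np.asarray(self.tsi_targets, dtype=float)
            if ((t < 0) | (t > 1)).any():
                raise ValueError("tsi targets must be in [0, 1]")
            if t.size != self.n_genes:
                raise ValueError("need one tsi target per gene")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.species is not None and len(self.species) != self.n_species:
            raise ValueError("species list length must equal n_species")

    @property
    def species_names(self) -> tuple[str, ...]:
        if self.species is not None:
            return tuple(self.species)
        if self.n_species <= len(_DEFAULT_SPECIES):
            return _DEFAULT_SPECIES[: self.n_species]
        return tuple(f"species_{i + 1:02d}" for i in range(self.n_species))

    def gene_omegas(self) -> np.ndarray:
        om = np.atleast_1d(np.asarray(self.omega, dtype=float))
        return np.full(self.n_genes, om[0]) if om.size == 1 else om.copy()

    def tissue_names(self) -> list[str]:
        return [f"tissue_{i + 1:02d}" for i in range(self.n_tissues)]

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGES[stage], int(self.seed)])


# ---------------------------------------------------------------------------
# reference gene set

def _codon_weights(beta: float) -> np.ndarray:
    w = np.exp(beta * _CODON_GC)
    return w / w.sum()


def _expected_gc(beta: float) -> float:
    w = _codon_weights(beta)
    return float((w * _CODON_GC).sum() / 3.0)


def _solve_beta(target_frac: float) -> float:
    """Bisection for the codon-GC tilt that hits a target GC fraction."""
    lo, hi = -12.0, 12.0
    if not (_expected_gc(lo) < target_frac < _expected_gc(hi)):
        raise SimulationError(f"GC target {100 * target_frac:.1f}% is unattainable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_gc(mid) < target_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_cds(length_codons: int, target_gc: float, rng: np.random.Generator,
                gene_id: str, max_tries: int = 30, tolerance: float = 5.0) -> tuple[str, float]:
    """One CDS: ATG start, stop end, no internal stops, GC near target."""
    try:
        beta = _solve_beta(target_gc / 100.0)
    except SimulationError as exc:
        raise SimulationError(f"gene {gene_id}: {exc}") from None
    w = _codon_weights(beta)
    stop_w = np.exp(beta * _STOP_GC)
    stop_w /= stop_w.sum()
    n_internal = length_codons - 2
    for _ in range(max_tries):
        idx = rng.choice(len(_SENSE_CODONS), size=n_internal, p=w)
        stop = _STOPS[rng.choice(3, p=stop_w)]
        cds = "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + stop
        gc = 100.0 * sum(1 for b in cds if b in "GC") / len(cds)
        if abs(gc - target_gc) <= tolerance:
            return cds, gc
    raise SimulationError(
        f"gene {gene_id}: could not realise GC target {target_gc:.1f}% "
        f"within +/-{tolerance} points at length {length_codons} codons"
    )


@dataclass
class ReferenceSet:
    """Reference CDS/proteins plus the per-gene truth skeleton."""

    cds: list[SeqRecord]
    proteins: list[SeqRecord]
    genes: pd.DataFrame  # gene, length_codons, target_gc, true_gc, true_omega, true_tsi

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene"])


def simulate_reference_geneset(config: SimulationConfig) -> ReferenceSet:
    """Generate the candidate missing-gene reference set.

    Per-gene GC targets come from the configured two-component mixture;
    GC is steered by exponentially tilting codon choice (solved by
    bisection per gene), never by rewriting a finished sequence. Each
    CDS starts with ATG, ends with a stop, and has no internal stops.
    """
    rng = config.rng("reference")
    gm = config.gc_mixture
    comp = rng.choice(2, size=config.n_genes, p=np.asarray(gm.weights))
    targets = np.clip(
        rng.normal(np.asarray(gm.means)[comp], np.asarray(gm.sds)[comp]), 25.0, 80.0
    )
    ld = config.length_dist
    shape = 4.0
    lengths = np.clip(
        np.round(rng.gamma(shape, ld.mean_codons / shape, size=config.n_genes)),
        ld.min_codons, ld.max_codons,
    ).astype(int)
    omegas = config.gene_omegas()
    if config.tsi_targets is not None:
        tsis = np.asarray(config.tsi_targets, dtype=float)
    else:
        tsis = rng.uniform(0.0, 1.0, size=config.n_genes)
    cds_records, pep_records, rows = [], [], []
    for g in range(config.n_genes):
        gene = f"gene_{g + 1:04d}"
        cds, gc = _sample_cds(int(lengths[g]), float(targets[g]), rng, gene)
        pep = translate(cds, strict=True)[:-1]  # drop terminator
        cds_records.append(SeqRecord(Seq(cds), id=gene, description=""))
        pep_records.append(SeqRecord(Seq(pep), id=gene, description=""))
        rows.append(
            {
                "gene": gene, "length_codons": int(lengths[g]),
                "target_gc": float(targets[g]), "true_gc": gc,
                "true_omega": float(omegas[g]), "true_tsi": float(tsis[g]),
            }
        )
    return ReferenceSet(cds=cds_records, proteins=pep_records, genes=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# species orthologs

def _evolve_cds(cds: str, omega: float, divergence: float, rng: np.random.Generator
                ) -> tuple[str, int, int]:
    """Proposal/acceptance codon substitution process.

    Start and stop codons are held fixed (ORFs must stay intact). The
    expected number of accepted changes is ``divergence`` per evolvable
    nucleotide site. Returns (diverged CDS, accepted syn, accepted nonsyn).
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_codons = len(codons)
    n_sites = 3 * (n_codons - 2)
    if n_sites <= 0 or divergence == 0:
        return cds, 0, 0
    n_target = rng.poisson(divergence * n_sites)
    if omega <= 1.0:
        p_syn, p_nonsyn = 1.0, omega
    else:
        p_syn, p_nonsyn = 1.0 / omega, 1.0
    n_syn = n_nonsyn = 0
    attempts = 0
    max_attempts = 200 * max(n_target, 1) + 1000
    while n_syn + n_nonsyn < n_target and attempts < max_attempts:
        attempts += 1
        site = int(rng.integers(0, n_sites))
        ci = 1 + site // 3
        pos = site % 3
        codon = codons[ci]
        base = codon[pos]
        alt = "ACGT".replace(base, "")[int(rng.integers(0, 3))]
        new_codon = codon[:pos] + alt + codon[pos + 1 :]
        new_aa = _CODON_TABLE[new_codon]
        if new_aa == "*":
            continue
        p_acc = p_syn if new_aa == _CODON_TABLE[codon] else p_nonsyn
        if rng.random() < p_acc:
            codons[ci] = new_codon
            if new_aa == _CODON_TABLE[codon]:
                n_syn += 1
            else:
                n_nonsyn += 1
    return "".join(codons), n_syn, n_nonsyn


@dataclass
class OrthologSet:
    """Per-species diverged CDS plus the (gene, species) truth table."""

    species_cds: dict[str, list[SeqRecord]]
    truth: pd.DataFrame  # gene, species, status, true_omega, true_gc, true_tsi, ...


def evolve_species_orthologs(reference: ReferenceSet, config: SimulationConfig) -> OrthologSet:
    """Assign per-(gene, species) status and emit diverged orthologs.

    ``lost`` genes emit nothing; ``hidden`` and ``annotated`` genes get
    a diverged CDS from the proposal/acceptance process. Accepted
    synonymous/nonsynonymous change counts are recorded so the realised
    omega is auditable.
    """
    status_rng = config.rng("status")
    evolve_rng = config.rng("evolve")
    species_cds: dict[str, list[SeqRecord]] = {sp: [] for sp in config.species_names}
    rows = []
    ref_by_gene = {r.id: str(r.seq) for r in reference.cds}
    for _, g in reference.genes.iterrows():
        gene = g["gene"]
        for sp in config.species_names:
            u = status_rng.random()
            if u < config.p_lost:
                status = "lost"
            elif status_rng.random() < config.p_hidden:
                status = "hidden"
            else:
                status = "annotated"
            n_syn = n_nonsyn = 0
            if status != "lost":
                cds, n_syn, n_nonsyn = _evolve_cds(
                    ref_by_gene[gene], float(g["true_omega"]), config.divergence, evolve_rng
                )
                species_cds[sp].append(SeqRecord(Seq(cds), id=gene, description=""))
            rows.append(
                {
                    "gene": gene, "species": sp, "status": status,
                    "true_omega": float(g["true_omega"]), "true_gc": float(g["true_gc"]),
                    "true_tsi": float(g["true_tsi"]),
                    "transcript_coverage": np.nan,
                    "n_syn_accepted": n_syn, "n_nonsyn_accepted": n_nonsyn,
                }
            )
    return OrthologSet(species_cds=species_cds, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# transcripts

def _random_seq(n: int, gc_frac: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@dataclass
class TranscriptSet:
    """Per-species transcript FASTA plus transcript-level truth."""

    transcripts: dict[str, list[SeqRecord]]
    transcript_truth: pd.DataFrame  # transcript_id, species, gene, coverage, ...


def fragment_transcripts(orthologs: OrthologSet, config: SimulationConfig) -> TranscriptSet:
    """Emulate incomplete de novo assembly.

    Every non-lost gene yields at least one transcript carrying a
    contiguous CDS fragment (coverage recorded in the truth tables,
    both per transcript and per (gene, species)); configurable
    fractions gain UTR-like flanks, are reverse-complemented, or gain a
    same-orientation near-duplicate.
    """
    f = config.fragmentation
    rng = config.rng("fragment")
    transcripts: dict[str, list[SeqRecord]] = {}
    rows = []
    coverage_updates: dict[tuple[str, str], float] = {}
    for sp in config.species_names:
        recs: list[SeqRecord] = []
        counter = 0
        for cds_rec in orthologs.species_cds[sp]:
            cds = str(cds_rec.seq)
            if rng.random() < f.full_length_prob:
                frag, coverage = cds, 1.0
            else:
                coverage = float(rng.uniform(f.min_coverage, 1.0))
                flen = max(30, int(round(coverage * len(cds))))
                flen = min(flen, len(cds))
                start = int(rng.integers(0, len(cds) - flen + 1))
                frag = cds[start : start + flen]
                coverage = flen / len(cds)
            seq = frag
            if rng.random() < f.utr_prob:
                lo, hi = f.utr_length
                seq = (
                    _random_seq(int(rng.integers(lo, hi + 1)), f.utr_gc / 100.0, rng)
                    + seq
                    + _random_seq(int(rng.integers(lo, hi + 1)), f.utr_gc / 100.0, rng)
                )
            revcomp = rng.random() < f.revcomp_prob
            if revcomp:
                seq = str(Seq(seq).reverse_complement())
            counter += 1
            tid = f"{sp}_tr{counter:05d}"
            recs.append(SeqRecord(Seq(seq), id=tid, description=""))
            rows.append(
                {
                    "transcript_id": tid, "species": sp, "gene": cds_rec.id,
                    "coverage": coverage, "revcomp": revcomp, "duplicate_of": "",
                }
            )
            coverage_updates[(cds_rec.id, sp)] = coverage
            if rng.random() < f.duplicate_prob:
                trim = int(rng.integers(0, int(f.max_duplicate_trim * len(seq)) + 1))
                dup_seq = seq[: len(seq) - trim] if trim else seq
                counter += 1
                did = f"{sp}_tr{counter:05d}"
                recs.append(SeqRecord(Seq(dup_seq), id=did, description=""))
                rows.append(
                    {
                        "transcript_id": did, "species": sp, "gene": cds_rec.id,
                        "coverage": coverage * len(dup_seq) / len(seq),
                        "revcomp": revcomp, "duplicate_of": tid,
                    }
                )
        transcripts[sp] = recs
    truth = orthologs.truth
    key = list(zip(truth["gene"], truth["species"]))
    truth = truth.assign(
        transcript_coverage=[coverage_updates.get(k, np.nan) for k in key]
    )
    orthologs.truth = truth
    return TranscriptSet(transcripts=transcripts, transcript_truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# expression

def tsi_profile(target: float, n_tissues: int, max_tissue: int = 0) -> np.ndarray:
    """Noise-free tissue profile whose Yanai index equals ``target`` exactly.

    The maximal tissue gets value 1 and every other tissue gets
    ``1 - target``: tau = (N-1)(1-(1-target))/(N-1) = target.
    """
    if not (0.0 <= target <= 1.0):
        raise ValueError("tsi target must be in [0, 1]")
    p = np.full(n_tissues, 1.0 - target)
    p[max_tissue] = 1.0
    return p


def simulate_expression(
    gene_ids: Sequence[str],
    tsi_targets: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a gene x tissue count table.

    Each gene's noise-free profile has value 1 in one randomly chosen
    maximal tissue and ``1 - tsi_target`` elsewhere, so its noise-free
    Yanai index equals the target exactly. Counts are negative-binomial
    (Poisson at dispersion 0) around abundance-scaled profiles, column-
    rescaled so expected per-tissue totals equal the library sizes.
    """
    rng = rng if rng is not None else config.rng("expression")
    genes = list(gene_ids)
    targets = np.asarray(tsi_targets, dtype=float)
    if targets.size != len(genes):
        raise ValueError("need one tsi target per gene")
    if ((targets < 0) | (targets > 1)).any():
        raise ValueError("tsi targets must be in [0, 1]")
    T = config.n_tissues
    lib = np.asarray(config.library_sizes, dtype=float)
    if lib.size == 1:
        lib = np.full(T, float(lib))
    if lib.size != T:
        raise ValueError("need one library size per tissue")
    max_tissue = rng.integers(0, T, size=len(genes))
    profile = np.stack(
        [tsi_profile(t, T, m) for t, m in zip(targets, max_tissue)]
    ) if len(genes) else np.zeros((0, T))
    abundance = rng.lognormal(mean=1.0, sigma=1.0, size=len(genes))
    mu = profile * abundance[:, None]
    col = mu.sum(axis=0)
    col[col == 0] = 1.0
    mu = mu * (lib / col)[None, :]
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=genes, columns=config.tissue_names())


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    transcripts: Sequence[SeqRecord],
    config: ReadSimConfig,
    rng: np.random.Generator,
    prefix: str = "read",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate Phred+33 reads with labelled QC-failure classes.

    ``frac_short`` of reads are shorter than 70 bp and ``frac_low_quality``
    carry more than 5% of bases below Q30; the rest pass both rules.
    Truth labels are returned alongside the reads.
    """
    pool = [str(t.seq) for t in transcripts if len(t.seq) > 0]
    if not pool:
        raise ValueError("need at least one non-empty transcript")
    records, rows = [], []
    for i in range(config.n_reads):
        u = rng.random()
        flag_short = u < config.frac_short
        flag_lowq = (not flag_short) and u < config.frac_short + config.frac_low_quality
        length = int(rng.integers(30, 70)) if flag_short else config.read_length
        src = pool[int(rng.integers(0, len(pool)))]
        if len(src) >= length:
            start = int(rng.integers(0, len(src) - length + 1))
            seq = src[start : start + length]
        else:
            seq = src + _random_seq(length - len(src), 0.5, rng)
        quals = [config.base_quality] * length
        if flag_lowq:
            n_low = max(int(np.ceil(config.low_quality_fraction_of_bases * length)), 1)
            low_pos = rng.choice(length, size=n_low, replace=False)
            for p in low_pos:
                quals[int(p)] = config.low_quality
        rid = f"{prefix}_{i + 1:06d}"
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
        rows.append(
            {"read_id": rid, "flagged_short": flag_short, "flagged_low_quality": flag_lowq}
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: ReferenceSet
    orthologs: OrthologSet
    transcripts: TranscriptSet
    expression: dict[str, pd.DataFrame]
    reads: dict[str, tuple[list[SeqRecord], pd.DataFrame]]
    annotations: dict[str, list[str]]

    @property
    def truth(self) -> pd.DataFrame:
        return self.orthologs.truth


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Run every generator stage under one seed."""
    reference = simulate_reference_geneset(config)
    orthologs = evolve_species_orthologs(reference, config)
    transcripts = fragment_transcripts(orthologs, config)
    expr_rng = config.rng("expression")
    tsi_by_gene = dict(zip(reference.genes["gene"], reference.genes["true_tsi"]))
    expression: dict[str, pd.DataFrame] = {}
    for sp in config.species_names:
        genes = [r.id for r in orthologs.species_cds[sp]]
        expression[sp] = simulate_expression(
            genes, [tsi_by_gene[g] for g in genes], config, rng=expr_rng
        )
    reads: dict[str, tuple[list[SeqRecord], pd.DataFrame]] = {}
    if config.reads is not None:
        read_rng = config.rng("reads")
        for sp in config.species_names:
            reads[sp] = simulate_reads(
                transcripts.transcripts[sp], config.reads, read_rng, prefix=f"{sp}_read"
            )
    truth = orthologs.truth
    annotations = {
        sp: sorted(truth.loc[(truth["species"] == sp) & (truth["status"] == "annotated"), "gene"])
        for sp in config.species_names
    }
    return SimulationResult(
        config=config, reference=reference, orthologs=orthologs,
        transcripts=transcripts, expression=expression, reads=reads,
        annotations=annotations,
    )


def write_outputs(result: SimulationResult, outdir) -> dict[str, Path]:
    """Write all artifacts as plain-text FASTA/FASTQ/TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _put(key, name):
        paths[key] = outdir / name
        return paths[key]

    write_fasta(result.reference.cds, _put("reference_cds", "reference_cds.fa"))
    write_fasta(result.reference.proteins, _put("reference_pep", "reference_pep.fa"))
    result.truth.to_csv(_put("truth", "truth.tsv"), sep="\t", index=False)
    result.transcripts.transcript_truth.to_csv(
        _put("transcript_truth", "transcript_truth.tsv"), sep="\t", index=False
    )
    result.reference.genes.to_csv(_put("genes", "reference_genes.tsv"), sep="\t", index=False)
    for sp in result.config.species_names:
        write_fasta(result.transcripts.transcripts[sp], _put(f"transcripts_{sp}", f"{sp}_transcripts.fa"))
        result.expression[sp].to_csv(_put(f"counts_{sp}", f"{sp}_counts.tsv"), sep="\t")
        ann = _put(f"annotation_{sp}", f"{sp}_annotation.txt")
        ann.write_text("".join(g + "\n" for g in result.annotations[sp]))
        if sp in result.reads:
            recs, truth = result.reads[sp]
            write_fastq(recs, _put(f"reads_{sp}", f"{sp}_reads.fq"))
            truth.to_csv(_put(f"read_truth_{sp}", f"{sp}_read_truth.tsv"), sep="\t", index=False)
    return paths
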