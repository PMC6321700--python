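"""Recovery matrix, confidence bins and ortholog hit ratio.

After the per-species best-hit search, each candidate missing gene is
scored by how many species' transcript sets recovered it:

* ``high``   — recovered in all species,
* ``medium`` — in more than half but not all (3-4 of 5),
* ``low``    — in at least one but at most half (1-2 of 5),
* ``absent`` — in none.

Transcript completeness is summarised by the ortholog hit ratio (OHR):
the length of the best recovered CDS divided by the reference CDS
length; values near 1 indicate complete transcripts (the raw ratio is
not clamped, so a recovered CDS longer than the reference gives
OHR > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BestHit",
    "RecoveryMatrix",
    "OhrScore",
    "build_recovery_matrix",
    "classify_confidence",
    "summarize_recovery",
    "ortholog_hit_ratio",
    "ohr_table",
]

BIN_LABELS = ("high", "medium", "low", "absent")


@dataclass(frozen=True)
class BestHit:
    """Best-hit evidence for one (gene, species) cell."""

    subject_id: str
    identity: float
    score: float
    best_cds_length: int  # nt length of the hit transcript's extracted ORF


@dataclass
class RecoveryMatrix:
    """Candidate genes x species presence table with best-hit evidence.

    ``cells`` is a long DataFrame (gene, species, recovered, subject_id,
    identity, score, best_cds_length); ``wide()`` gives the boolean
    gene x species view.
    """

    genes: list[str]
    species: list[str]
    cells: pd.DataFrame

    def wide(self) -> pd.DataFrame:
        w = self.cells.pivot(index="gene", columns="species", values="recovered")
        return w.reindex(index=self.genes, columns=self.species).fillna(False).astype(bool)

    def recovered_counts(self) -> pd.Series:
        """Number of species each gene was recovered in."""
        return self.wide().sum(axis=1)


def build_recovery_matrix(
    hits: Mapping[str, Mapping[str, BestHit]],
    candidate_genes: Sequence[str],
) -> RecoveryMatrix:
    """Assemble the genes x species matrix from per-species hit tables.

    ``hits`` maps species -> {gene -> BestHit}; genes with no hit
    anywhere still get (all-absent) rows. A hit for a gene outside the
    candidate list is an error.
    """
    genes = list(candidate_genes)
    gene_set = set(genes)
    if len(gene_set) != len(genes):
        raise ValueError("candidate gene ids must be unique")
    species = list(hits.keys())
    rows = []
    for sp in species:
        for gene in hits[sp]:
            if gene not in gene_set:
                raise ValueError(f"hit references unknown candidate gene {gene!r} in {sp!r}")
    for gene in genes:
        for sp in species:
            h = hits[sp].get(gene)
            rows.append(
                {
                    "gene": gene, "species": sp, "recovered": h is not None,
                    "subject_id": h.subject_id if h else "",
                    "identity": h.identity if h else np.nan,
                    "score": h.score if h else np.nan,
                    "best_cds_length": h.best_cds_length if h else 0,
                }
            )
    return RecoveryMatrix(genes=genes, species=species, cells=pd.DataFrame(rows))


def classify_confidence(recovered_count: int, total_species: int = 5) -> str:
    """Map a recovered-species count to a confidence bin.

    For any species total: high = all, medium = more than half but not
    all, low = at least one but at most half, absent = none.
    """
    if not (0 <= recovered_count <= total_species):
        raise ValueError(
            f"recovered_count {recovered_count} outside [0, {total_species}]"
        )
    if recovered_count == total_species:
        return "high"
    if recovered_count == 0:
        return "absent"
    if recovered_count > total_species / 2:
        return "medium"
    return "low"


def summarize_recovery(matrix: RecoveryMatrix) -> dict:
    """Bin counts/percentages and per-species recovery totals.

    The percentage denominator is always the actual candidate-list
    length (reported as ``n_candidates``); bin counts partition the
    candidate set exactly.
    """
    counts = matrix.recovered_counts()
    total_species = len(matrix.species)
    bins = counts.map(lambda c: classify_confidence(int(c), total_species))
    n = len(matrix.genes)
    bin_rows = []
    for label in BIN_LABELS:
        c = int((bins == label).sum())
        bin_rows.append({"bin": label, "count": c, "percent": round(100.0 * c / n, 2)})
    per_species = matrix.wide().sum(axis=0).astype(int)
    return {
        "n_candidates": n,
        "bin_table": pd.DataFrame(bin_rows),
        "bins_by_gene": bins,
        "per_species_recovered": per_species,
        "recovered_any": int((counts > 0).sum()),
    }


@dataclass(frozen=True)
class OhrScore:
    gene_id: str
    species_id: str
    best_cds_length: int
    reference_length: int
    ohr: float


def ortholog_hit_ratio(
    best_cds_length: int, reference_length: int,
    gene_id: str = "gene", species_id: str = "species",
) -> OhrScore:
    """OHR = best recovered CDS length / reference CDS length (unclamped)."""
    if best_cds_length <= 0 or reference_length <= 0:
        raise ValueError("lengths must be positive")
    return OhrScore(
        gene_id=gene_id, species_id=species_id,
        best_cds_length=int(best_cds_length), reference_length=int(reference_length),
        ohr=best_cds_length / reference_length,
    )


def ohr_table(matrix: RecoveryMatrix, reference_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-(gene, species) OHR for every recovered cell."""
    rows = []
    for _, cell in matrix.cells[matrix.cells["recovered"]].iterrows():
        ref_len = reference_lengths.get(cell["gene"])
        if ref_len is None:
            raise ValueError(f"no reference length for gene {cell['gene']!r}")
        s = ortholog_hit_ratio(
            int(cell["best_cds_length"]), int(ref_len),
            gene_id=cell["gene"], species_id=cell["species"],
        )
        rows.append(
            {
                "gene": s.gene_id, "species": s.species_id,
                "best_cds_length": s.best_cds_length,
                "reference_length": s.reference_length, "ohr": s.ohr,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "species", "best_cds_length", "reference_length", "ohr"])
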