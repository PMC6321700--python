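"""Expression normalisation and tissue-specificity statistics.

Implements RPKM and TPM normalisation of gene x tissue count tables,
Yanai's tissue-specificity index

    tau = sum_i (1 - v_i / v_max) / (N - 1)

over N tissues (0 = uniform expression, 1 = single-tissue expression),
the 3-fold "highly expressed in a tissue" rule, and per-tissue
enrichment summaries contrasting two gene sets.

All matrix operations take a pandas DataFrame with genes as rows and
tissues as columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TsiResult",
    "rpkm",
    "tpm",
    "tsi",
    "tsi_table",
    "highly_expressed",
    "tissue_enrichment",
]

#: Below this many tissues the index loses resolution; a guard warns.
TSI_MIN_TISSUES = 10


def _check_dims(counts: pd.DataFrame, lengths: pd.Series) -> pd.Series:
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing effective lengths for genes {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    return lengths.astype(float)


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million: counts·1e9 / (library · length).

    ``library_sizes`` defaults to the per-tissue column sums.
    """
    lengths = _check_dims(counts, lengths)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts.astype(float).mul(1e9).div(library_sizes, axis=1).div(lengths, axis=0)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; every tissue column sums to 1e6.

    An all-zero tissue column stays zero (with a warning) rather than
    dividing by zero.
    """
    lengths = _check_dims(counts, lengths)
    rate = counts.astype(float).div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom[denom == 0].index
    if len(zero_cols):
        warnings.warn(f"all-zero tissue columns: {list(zero_cols)}; TPM left at 0")
        denom = denom.replace(0, np.nan)
    out = rate.div(denom, axis=1).mul(1e6)
    return out.fillna(0.0)


@dataclass(frozen=True)
class TsiResult:
    gene_id: str
    tsi: float
    n_tissues: int
    max_tissue: str
    highly_expressed_tissues: frozenset


def tsi(values, gene_id: str = "gene", warn_few_tissues: bool = True) -> TsiResult:
    """Yanai's tau for one gene's expression profile across tissues.

    ``values`` is a pandas Series (index = tissues) or array of
    non-negative values. An all-zero profile yields ``tsi = nan``.
    Ties in the maximal tissue go to the first tissue in column order.
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 2:
        raise ValueError("TSI requires at least 2 tissues")
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    if warn_few_tissues and len(v) <= TSI_MIN_TISSUES:
        warnings.warn(
            f"TSI computed over {len(v)} tissues; values lose resolution "
            f"with <= {TSI_MIN_TISSUES} tissues"
        )
    vmax = v.max()
    if vmax == 0:
        return TsiResult(gene_id, float("nan"), len(v), str(v.index[0]), frozenset())
    tau = float((1.0 - v / vmax).sum() / (len(v) - 1))
    max_tissue = str(v.idxmax())  # first occurrence on ties
    high = highly_expressed(v)
    return TsiResult(gene_id, tau, len(v), max_tissue, frozenset(high))


def tsi_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TSI over a genes x tissues matrix (one guard warning)."""
    if matrix.shape[1] <= TSI_MIN_TISSUES:
        warnings.warn(
            f"TSI computed over {matrix.shape[1]} tissues; values lose "
            f"resolution with <= {TSI_MIN_TISSUES} tissues"
        )
    if matrix.empty:
        return pd.DataFrame(
            columns=["tsi", "n_tissues", "max_tissue", "n_highly_expressed"],
            index=pd.Index([], name="gene"),
        )
    rows = []
    for gene, v in matrix.iterrows():
        r = tsi(v, gene_id=str(gene), warn_few_tissues=False)
        rows.append(
            {
                "gene": r.gene_id,
                "tsi": r.tsi,
                "n_tissues": r.n_tissues,
                "max_tissue": r.max_tissue,
                "n_highly_expressed": len(r.highly_expressed_tissues),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def highly_expressed(values, fold: float = 3.0, inclusive: bool = True) -> list:
    """Tissues where a gene counts as highly expressed.

    A tissue qualifies when its value reaches ``fold`` times the mean
    over all tissues (the focal tissue included in the mean; boundary
    inclusive by default). An all-zero profile qualifies nowhere.
    """
    v = pd.Series(values, dtype=float)
    m = v.mean()
    if m == 0:
        return []
    mask = v >= fold * m if inclusive else v > fold * m
    return list(v.index[mask])


def tissue_enrichment(
    matrix: pd.DataFrame, genes_a, genes_b, label_a: str = "A", label_b: str = "B"
) -> pd.DataFrame:
    """Per-tissue contrast of two gene sets.

    For each set and tissue: ``top_fraction`` is the fraction of the
    set's genes whose maximum expression falls in that tissue (ties over
    k maximal tissues contribute 1/k each, so fractions sum to 1), and
    ``expressed_fraction`` is the fraction of the set's genes with any
    expression (> 0) in that tissue.
    """
    out = pd.DataFrame(index=matrix.columns)
    for label, genes in ((label_a, genes_a), (label_b, genes_b)):
        genes = [g for g in genes]
        if not genes:
            raise ValueError(f"gene set {label!r} is empty")
        sub = matrix.loc[genes]
        top = pd.Series(0.0, index=matrix.columns)
        for _, v in sub.iterrows():
            vmax = v.max()
            if vmax == 0:
                continue
            winners = v.index[v == vmax]
            top[winners] += 1.0 / len(winners)
        n_scored = top.sum()
        out[f"top_fraction_{label}"] = top / n_scored if n_scored else 0.0
        out[f"expressed_fraction_{label}"] = (sub > 0).mean(axis=0)
    return out
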