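"""End-to-end pipeline: simulate -> QC -> collapse -> ORFs -> search ->
classify -> composition / expression / Ka-Ks -> report.

Stages hand data to each other through plain-text files (FASTA/FASTQ/
TSV) in one output directory, so any stage can be re-run from the
previous stage's outputs. A JSON run manifest records, per stage, the
parameter snapshot, input/output files and record counts; identical
config + seed reproduces identical manifest counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import composition as comp_mod
from . import expression as expr_mod
from . import evolution, homology, recovery, seqio_qc, synthetic_data

__all__ = ["RunConfig", "PipelineError", "STAGES", "run_pipeline", "write_report"]

log = logging.getLogger("avirescue")

STAGES = (
    "simulate", "qc", "collapse", "orfs", "search", "classify",
    "composition", "expression", "kaks", "report",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All pipeline parameters plus the output directory."""

    outdir: Path = Path("avirescue_run")
    sim: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    read_filter: seqio_qc.ReadFilterConfig = field(default_factory=seqio_qc.ReadFilterConfig)
    collapse_identity: float = 0.95
    collapse_coverage: float = 0.8
    orf_min_aa: int = 30
    orf_require_start: bool = False
    min_identity: float = 40.0
    max_evalue: float = 1e-10
    tsi_threshold: float = 0.9
    highly_expressed_fold: float = 3.0
    kaks_species: str | None = None  # default: first species
    background_n: int = 100  # genome-wide-like cohort for the Ka/Ks contrast
    background_omega: float = 0.99

    def __post_init__(self):
        self.outdir = Path(self.outdir)

    @property
    def species(self) -> tuple[str, ...]:
        return self.sim.species_names

    def path(self, name: str) -> Path:
        return self.outdir / name


def _require(cfg: RunConfig, name: str, produced_by: str) -> Path:
    p = cfg.path(name)
    if not p.exists():
        raise PipelineError(
            f"missing input {p}; run stage {produced_by!r} first"
        )
    return p


def _entry(stage, params, inputs, outputs, n_in, n_out):
    return {
        "stage": stage,
        "params": params,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "records_in": n_in,
        "records_out": n_out,
        "status": "ok",
    }


def stage_simulate(cfg: RunConfig) -> dict:
    log.info("[simulate] %d genes x %d species, seed %d",
             cfg.sim.n_genes, cfg.sim.n_species, cfg.sim.seed)
    result = synthetic_data.simulate_all(cfg.sim)
    paths = synthetic_data.write_outputs(result, cfg.outdir)
    n_tr = sum(len(v) for v in result.transcripts.transcripts.values())
    return _entry(
        "simulate",
        {"seed": cfg.sim.seed, "n_genes": cfg.sim.n_genes, "n_species": cfg.sim.n_species,
         "p_hidden": cfg.sim.p_hidden, "p_lost": cfg.sim.p_lost,
         "omega": str(cfg.sim.omega), "divergence": cfg.sim.divergence},
        [], sorted(paths.values()), cfg.sim.n_genes, n_tr,
    )


def stage_qc(cfg: RunConfig) -> dict:
    inputs, outputs = [], []
    n_in = n_out = 0
    for sp in cfg.species:
        fq = cfg.path(f"{sp}_reads.fq")
        if not fq.exists():
            continue
        inputs.append(fq)
        reads = seqio_qc.read_fastq(fq)
        kept, qc_log = seqio_qc.filter_reads(reads, cfg.read_filter)
        n_in += len(reads)
        n_out += len(kept)
        out_fq = cfg.path(f"{sp}_reads_filtered.fq")
        seqio_qc.write_fastq(kept, out_fq)
        pd.DataFrame(qc_log).to_csv(cfg.path(f"{sp}_qc_report.tsv"), sep="\t", index=False)
        outputs += [out_fq, cfg.path(f"{sp}_qc_report.tsv")]
        log.info("[qc] %s: kept %d/%d reads", sp, len(kept), len(reads))
    return _entry("qc", dataclasses.asdict(cfg.read_filter), inputs, outputs, n_in, n_out)


def stage_collapse(cfg: RunConfig) -> dict:
    inputs, outputs = [], []
    n_in = n_out = 0
    for sp in cfg.species:
        fa = _require(cfg, f"{sp}_transcripts.fa", "simulate")
        inputs.append(fa)
        records = seqio_qc.read_fasta(fa, alphabet="nucleotide")
        if records:
            reps, cluster_map = seqio_qc.collapse_redundancy(
                records, cfg.collapse_identity, cfg.collapse_coverage
            )
        else:
            reps, cluster_map = [], {}
        n_in += len(records)
        n_out += len(reps)
        out_fa = cfg.path(f"{sp}_collapsed.fa")
        seqio_qc.write_fasta(reps, out_fa)
        pd.DataFrame(
            [{"member_id": m, "representative_id": r} for m, r in sorted(cluster_map.items())]
        ).to_csv(cfg.path(f"{sp}_clusters.tsv"), sep="\t", index=False)
        outputs += [out_fa, cfg.path(f"{sp}_clusters.tsv")]
        log.info("[collapse] %s: %d -> %d transcripts", sp, len(records), len(reps))
    return _entry(
        "collapse",
        {"identity": cfg.collapse_identity, "coverage": cfg.collapse_coverage},
        inputs, outputs, n_in, n_out,
    )


def stage_orfs(cfg: RunConfig) -> dict:
    inputs, outputs = [], []
    n_in = n_out = 0
    for sp in cfg.species:
        fa = _require(cfg, f"{sp}_collapsed.fa", "collapse")
        inputs.append(fa)
        records = seqio_qc.read_fasta(fa, alphabet="nucleotide")
        n_in += len(records)
        peps, cds, rows = [], [], []
        for rec in records:
            orf = seqio_qc.find_longest_orf(
                str(rec.seq), min_length_aa=cfg.orf_min_aa,
                require_start=cfg.orf_require_start, transcript_id=rec.id,
            )
            if orf is None:
                continue
            peps.append(SeqRecord(Seq(orf.peptide), id=rec.id, description=""))
            cds.append(SeqRecord(Seq(orf.orf_sequence), id=rec.id, description=""))
            rows.append(
                {
                    "transcript_id": rec.id, "strand": orf.strand,
                    "orf_start_1based": orf.orf_start + 1, "orf_end": orf.orf_end,
                    "orf_nt_length": orf.orf_end - orf.orf_start,
                    "peptide_length": len(orf.peptide),
                }
            )
        n_out += len(peps)
        pep_fa = cfg.path(f"{sp}_peptides.faa")
        cds_fa = cfg.path(f"{sp}_orf_cds.fna")
        seqio_qc.write_fasta(peps, pep_fa)
        seqio_qc.write_fasta(cds, cds_fa)
        pd.DataFrame(
            rows,
            columns=["transcript_id", "strand", "orf_start_1based", "orf_end",
                     "orf_nt_length", "peptide_length"],
        ).to_csv(cfg.path(f"{sp}_orfs.tsv"), sep="\t", index=False)
        outputs += [pep_fa, cds_fa, cfg.path(f"{sp}_orfs.tsv")]
        log.info("[orfs] %s: %d/%d transcripts with ORFs", sp, len(peps), len(records))
    return _entry(
        "orfs",
        {"min_aa": cfg.orf_min_aa, "require_start": cfg.orf_require_start},
        inputs, outputs, n_in, n_out,
    )


_HITS_COLS = [
    "qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart",
    "evalue", "score", "best_cds_length",
]


def stage_search(cfg: RunConfig) -> dict:
    ref_fa = _require(cfg, "reference_pep.fa", "simulate")
    refs = seqio_qc.read_fasta(ref_fa, alphabet="protein")
    scheme = homology.ScoringScheme()
    inputs, outputs = [ref_fa], []
    n_hits = 0
    for sp in cfg.species:
        pep_fa = _require(cfg, f"{sp}_peptides.faa", "orfs")
        orf_tab = pd.read_csv(_require(cfg, f"{sp}_orfs.tsv", "orfs"), sep="\t")
        cds_len = dict(zip(orf_tab["transcript_id"], orf_tab["orf_nt_length"]))
        inputs.append(pep_fa)
        peptides = [(r.id, str(r.seq)) for r in seqio_qc.read_fasta(pep_fa, alphabet="protein")]
        rows = []
        for ref in refs:
            hit = homology.search_best_hit(
                (ref.id, str(ref.seq)), peptides,
                min_identity=cfg.min_identity, max_e=cfg.max_evalue, scheme=scheme,
            )
            if hit is None:
                continue
            rows.append(
                {
                    "qseqid": hit.query_id, "sseqid": hit.subject_id,
                    "pident": round(hit.identity, 2), "length": hit.aligned_length,
                    "qstart": hit.query_start + 1,
                    "qend": hit.query_start + sum(c != "-" for c in hit.query_aligned),
                    "sstart": hit.subject_start + 1,
                    "evalue": hit.e_value, "score": hit.score,
                    "best_cds_length": int(cds_len[hit.subject_id]),
                }
            )
        n_hits += len(rows)
        out = cfg.path(f"{sp}_hits.tsv")
        pd.DataFrame(rows, columns=_HITS_COLS).to_csv(out, sep="\t", index=False)
        outputs.append(out)
        log.info("[search] %s: %d/%d candidates with best hits", sp, len(rows), len(refs))
    return _entry(
        "search",
        {"min_identity": cfg.min_identity, "max_evalue": cfg.max_evalue},
        inputs, outputs, len(refs) * len(cfg.species), n_hits,
    )


def _load_hits(cfg: RunConfig) -> dict[str, dict[str, recovery.BestHit]]:
    hits: dict[str, dict[str, recovery.BestHit]] = {}
    for sp in cfg.species:
        tab = pd.read_csv(_require(cfg, f"{sp}_hits.tsv", "search"), sep="\t")
        hits[sp] = {
            r["qseqid"]: recovery.BestHit(
                subject_id=r["sseqid"], identity=r["pident"],
                score=r["score"], best_cds_length=int(r["best_cds_length"]),
            )
            for _, r in tab.iterrows()
        }
    return hits


def stage_classify(cfg: RunConfig) -> dict:
    ref_fa = _require(cfg, "reference_cds.fa", "simulate")
    ref_cds = seqio_qc.read_fasta(ref_fa, alphabet="nucleotide")
    candidates = [r.id for r in ref_cds]
    ref_len = {r.id: len(r.seq) for r in ref_cds}
    hits = _load_hits(cfg)
    matrix = recovery.build_recovery_matrix(hits, candidates)
    summary = recovery.summarize_recovery(matrix)
    ohr = recovery.ohr_table(matrix, ref_len)
    wide = matrix.wide()
    wide_out = wide.copy()
    wide_out["recovered_in"] = matrix.recovered_counts()
    wide_out["bin"] = summary["bins_by_gene"]
    outputs = [cfg.path("recovery_matrix.tsv"), cfg.path("bin_summary.tsv"), cfg.path("ohr.tsv")]
    wide_out.to_csv(outputs[0], sep="\t")
    summary["bin_table"].to_csv(outputs[1], sep="\t", index=False)
    ohr.to_csv(outputs[2], sep="\t", index=False)
    log.info("[classify] bins: %s", dict(zip(summary["bin_table"]["bin"], summary["bin_table"]["count"])))
    return _entry(
        "classify", {"total_species": len(cfg.species)},
        [ref_fa] + [cfg.path(f"{sp}_hits.tsv") for sp in cfg.species],
        outputs, len(candidates), int(summary["recovered_any"]),
    )


def stage_composition(cfg: RunConfig) -> dict:
    inputs, frames = [], []
    for sp in cfg.species:
        hits = pd.read_csv(_require(cfg, f"{sp}_hits.tsv", "search"), sep="\t")
        cds_fa = _require(cfg, f"{sp}_orf_cds.fna", "orfs")
        inputs += [cfg.path(f"{sp}_hits.tsv"), cds_fa]
        seqs = {r.id: str(r.seq) for r in seqio_qc.read_fasta(cds_fa, alphabet="nucleotide")}
        records = [(r["qseqid"], seqs[r["sseqid"]]) for _, r in hits.iterrows()]
        if not records:
            continue
        tab = comp_mod.composition_table(records)
        tab.insert(0, "species", sp)
        frames.append(tab)
    if frames:
        full = pd.concat(frames, ignore_index=True)
    else:
        full = pd.DataFrame(columns=["species", "id", "gc_percent"])
    comp_out = cfg.path("composition.tsv")
    full.to_csv(comp_out, sep="\t", index=False)
    bins_rows = []
    for sp, sub in full.groupby("species"):
        b = comp_mod.gc_bins(sub["gc_percent"])
        b.insert(0, "species", sp)
        bins_rows.append(b)
    bins = pd.concat(bins_rows, ignore_index=True) if bins_rows else pd.DataFrame()
    bins_out = cfg.path("gc_bins.tsv")
    bins.to_csv(bins_out, sep="\t", index=False)
    return _entry("composition", {}, inputs, [comp_out, bins_out], len(full), len(full))


def stage_expression(cfg: RunConfig) -> dict:
    ref_fa = _require(cfg, "reference_cds.fa", "simulate")
    ref_len = pd.Series({r.id: len(r.seq) for r in seqio_qc.read_fasta(ref_fa)})
    inputs, outputs, summary_rows = [ref_fa], [], []
    n_genes = 0
    for sp in cfg.species:
        counts_path = _require(cfg, f"{sp}_counts.tsv", "simulate")
        inputs.append(counts_path)
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        if counts.empty:
            tsis = expr_mod.tsi_table(pd.DataFrame())
        else:
            norm = expr_mod.rpkm(counts, ref_len.reindex(counts.index))
            tsis = expr_mod.tsi_table(norm)
        frac = float((tsis["tsi"] > cfg.tsi_threshold).mean()) if len(tsis) else float("nan")
        out = cfg.path(f"{sp}_tsi.tsv")
        tsis.to_csv(out, sep="\t")
        outputs.append(out)
        n_genes += len(tsis)
        summary_rows.append(
            {
                "species": sp, "n_genes": len(tsis),
                "mean_tsi": float(tsis["tsi"].mean()),
                f"fraction_tsi_gt_{cfg.tsi_threshold:g}": round(frac, 4),
            }
        )
        log.info("[expression] %s: %.1f%% of genes with TSI > %g",
                 sp, 100 * frac, cfg.tsi_threshold)
    summary = pd.DataFrame(summary_rows)
    out = cfg.path("tsi_summary.tsv")
    summary.to_csv(out, sep="\t", index=False)
    outputs.append(out)
    return _entry("expression", {"tsi_threshold": cfg.tsi_threshold}, inputs, outputs, n_genes, n_genes)


def stage_kaks(cfg: RunConfig) -> dict:
    """Ka/Ks of recovered genes vs a background ortholog cohort.

    The recovered ("missing gene") arm aligns each reference CDS to the
    best-hit transcript ORF in one species. The background
    ("genome-wide") arm is a fresh cohort simulated at
    ``background_omega``, standing in for annotated single-copy
    orthologs.
    """
    sp = cfg.kaks_species or cfg.species[0]
    ref_fa = _require(cfg, "reference_cds.fa", "simulate")
    ref_cds = {r.id: str(r.seq) for r in seqio_qc.read_fasta(ref_fa)}
    hits = pd.read_csv(_require(cfg, f"{sp}_hits.tsv", "search"), sep="\t")
    cds_fa = _require(cfg, f"{sp}_orf_cds.fna", "orfs")
    orf_cds = {r.id: str(r.seq) for r in seqio_qc.read_fasta(cds_fa)}
    rows, missing_vals = [], []
    for _, h in hits.iterrows():
        try:
            res = evolution.kaks_pair(
                ref_cds[h["qseqid"]], orf_cds[h["sseqid"]],
                id_a=h["qseqid"], id_b=h["sseqid"],
            )
        except ValueError:
            continue
        rows.append(
            {
                "gene": res.id_a, "subject": res.id_b, "species": sp,
                "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                "ka": res.ka, "ks": res.ks, "ratio": res.ratio, "status": res.status,
            }
        )
        missing_vals.append(res.ratio)
    out = cfg.path("kaks.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    # background cohort: evolve fresh orthologs at the background omega
    bg_cfg = dataclasses.replace(
        cfg.sim, n_genes=cfg.background_n, n_species=1, species=("background",),
        omega=cfg.background_omega, p_lost=0.0, p_hidden=0.0,
        seed=cfg.sim.seed + 104729,
    )
    bg_ref = synthetic_data.simulate_reference_geneset(bg_cfg)
    bg_orth = synthetic_data.evolve_species_orthologs(bg_ref, bg_cfg)
    bg_ref_cds = {r.id: str(r.seq) for r in bg_ref.cds}
    bg_vals = []
    for rec in bg_orth.species_cds["background"]:
        res = evolution.kaks_pair(bg_ref_cds[rec.id], str(rec.seq), id_a=rec.id, id_b=rec.id)
        bg_vals.append(res.ratio)
    summary = {"species": sp, "n_missing": len(missing_vals), "n_background": len(bg_vals)}
    try:
        cmpres = evolution.compare_groups(missing_vals, bg_vals)
        summary.update(
            mean_missing=cmpres.mean_a, mean_background=cmpres.mean_b,
            n_excluded_missing=cmpres.n_excluded_a, n_excluded_background=cmpres.n_excluded_b,
            t_statistic=cmpres.t_statistic, p_value=cmpres.p_value,
        )
    except ValueError as exc:
        summary.update(error=str(exc))
    out2 = cfg.path("kaks_summary.tsv")
    pd.DataFrame([summary]).to_csv(out2, sep="\t", index=False)
    log.info("[kaks] missing mean %.3f vs background mean %.3f",
             summary.get("mean_missing", float("nan")),
             summary.get("mean_background", float("nan")))
    return _entry(
        "kaks",
        {"species": sp, "background_n": cfg.background_n,
         "background_omega": cfg.background_omega},
        [ref_fa, cfg.path(f"{sp}_hits.tsv"), cds_fa], [out, out2],
        len(hits), len(rows),
    )


def write_report(cfg: RunConfig) -> Path:
    """Assemble the human-readable markdown summary from stage TSVs."""
    lines = ["# Missing-gene recovery report", ""]
    bin_path = cfg.path("bin_summary.tsv")
    if bin_path.exists():
        bins = pd.read_csv(bin_path, sep="\t")
        n = int(bins["count"].sum())
        lines += [f"Candidate genes: {n}", "", "## Confidence bins", ""]
        if n == 0:
            lines.append("Zero candidate genes; nothing to classify.")
        else:
            lines.append(bins.to_markdown(index=False))
        rm = cfg.path("recovery_matrix.tsv")
        if rm.exists():
            wide = pd.read_csv(rm, sep="\t", index_col=0)
            sp_cols = [c for c in wide.columns if c not in ("recovered_in", "bin")]
            lines += ["", "## Recovered per species", ""]
            for sp in sp_cols:
                lines.append(f"- {sp}: {int(wide[sp].sum())}")
    for sp in cfg.species:
        fa = cfg.path(f"{sp}_collapsed.fa")
        if fa.exists() and (records := seqio_qc.read_fasta(fa)):
            stats = seqio_qc.assembly_stats(records)
            lines += [
                "",
                f"## Assembly stats ({sp}): {stats.n_sequences} transcripts, "
                f"N50 {stats.n50} bp, mean {stats.mean_length:.0f} bp",
            ]
    gc_path = cfg.path("gc_bins.tsv")
    if gc_path.exists() and gc_path.stat().st_size > 1:
        gc = pd.read_csv(gc_path, sep="\t")
        if len(gc):
            lines += ["", "## GC bins (recovered CDS)", "", gc.to_markdown(index=False)]
    tsi_path = cfg.path("tsi_summary.tsv")
    if tsi_path.exists():
        tsi = pd.read_csv(tsi_path, sep="\t")
        lines += ["", "## Tissue specificity", "", tsi.to_markdown(index=False)]
    kk = cfg.path("kaks_summary.tsv")
    if kk.exists():
        kaks = pd.read_csv(kk, sep="\t")
        lines += ["", "## Ka/Ks contrast (recovered vs background)", "", kaks.to_markdown(index=False)]
    truth_path = cfg.path("truth.tsv")
    if truth_path.exists() and bin_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        lost_everywhere = int((truth.groupby("gene")["status"].apply(lambda s: (s == "lost").all())).sum())
        bins = pd.read_csv(bin_path, sep="\t").set_index("bin")["count"]
        lines += [
            "",
            "## Truth audit",
            "",
            f"- genes lost in all species (truth): {lost_everywhere}",
            f"- genes classified absent: {int(bins.get('absent', 0))}",
        ]
    out = cfg.path("report.md")
    out.write_text("\n".join(lines) + "\n")
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "collapse": stage_collapse,
    "orfs": stage_orfs,
    "search": stage_search,
    "classify": stage_classify,
    "composition": stage_composition,
    "expression": stage_expression,
    "kaks": stage_kaks,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the manifest."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = cfg.path("manifest.json")
    manifest: dict = {"seed": cfg.sim.seed, "stages": {}}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            pass
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "report":
            write_report(cfg)
            manifest["stages"]["report"] = {
                "stage": "report", "outputs": [str(cfg.path("report.md"))], "status": "ok",
            }
            continue
        manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg)
    manifest["seed"] = cfg.sim.seed
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
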