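"""End-to-end missing-gene recovery on a small synthetic study.

Simulates 40 candidate genes across 5 bird-like species (some genes
hidden from the mock annotations, some truly lost), assembles the
pipeline stages (collapse -> ORFs -> homology search -> classification)
and prints the confidence-bin table. "high" means recovered in all
species, "absent" means recovered in none — truly lost genes can only
be absent, because they emit no transcripts.
"""

import tempfile
from pathlib import Path

import pandas as pd

from avirescue.pipeline import RunConfig, run_pipeline
from avirescue.synthetic_data import SimulationConfig

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(
        outdir=Path(tmp) / "run",
        sim=SimulationConfig(n_genes=40, n_species=5, p_hidden=0.3, p_lost=0.1, seed=11),
        background_n=40,
    )
    run_pipeline(cfg, stages=["simulate", "collapse", "orfs", "search", "classify"])
    bins = pd.read_csv(cfg.path("bin_summary.tsv"), sep="\t")
    ohr = pd.read_csv(cfg.path("ohr.tsv"), sep="\t")
    print("Confidence bins over", bins["count"].sum(), "candidate genes:")
    print(bins.to_string(index=False))
    print(f"\nMedian ortholog hit ratio: {ohr['ohr'].median():.3f} "
          "(1.0 = the recovered CDS is as long as the reference)")
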