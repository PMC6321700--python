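# avirescue

Recovering presumed-missing avian genes from de novo assembled
transcriptomes.

Hundreds of genes that are present across vertebrates appear to be
absent from bird genome assemblies and annotations. Many of them are
not truly lost — they hide in GC-rich, hard-to-assemble regions and
surface only in deeply sequenced transcriptomes. `avirescue`
implements the complete desk-scale analysis for testing which
candidate "missing" genes can be recovered from assembled transcripts:

* **Read QC** — whole-read filtering (drop reads < 70 bp or with > 5%
  of bases below Q30).
* **Redundancy collapse** — greedy clustering of near-identical
  transcripts (CD-HIT-style `-c 0.95 -aS 0.8` semantics, exact
  alignment instead of word heuristics).
* **ORF extraction** — longest open reading frame over all six frames,
  with or without a required ATG start.
* **Homology search** — Smith–Waterman local alignment with affine
  gaps (BLOSUM62, 11/1), Karlin–Altschul E-values
  `E = K·m·n·e^(−λS)`, and best-hit selection under the recovery
  filters identity > 40% and E ≤ 1e-10.
* **Recovery classification** — per-gene confidence bins: *high*
  (recovered in all species), *medium* (more than half), *low* (at
  least one), *absent* (none); transcript completeness scored by the
  ortholog hit ratio, OHR = length of the best recovered CDS / length
  of the reference CDS.
* **Composition** — GC%, AT-rich flags (AT% > 60), GC bins, and
  GC-stretch (maximal G/C run) profiles.
* **Expression** — RPKM/TPM normalisation, Yanai's tissue-specificity
  index `τ = Σᵢ(1 − vᵢ/v_max)/(N − 1)` (0 = uniform, 1 =
  single-tissue), and the 3-fold highly-expressed rule.
* **Molecular evolution** — codon-aware pairwise alignment
  (Needleman–Wunsch on peptides, back-translated) and NG86 Ka/Ks:
  fractional synonymous/nonsynonymous site counts, pathway-averaged
  difference counts, Jukes–Cantor correction
  `d = −(3/4)·ln(1 − (4/3)p)`, plus Welch t-test group contrasts.
* **Synthetic study system** — a ground-truth generator standing in
  for the real multi-species RNA-seq compendium: candidate genes with
  a bimodal GC distribution, per-species annotated/hidden/lost status,
  codon-level divergence at a target dN/dS (ω), fragmented transcripts
  with UTRs/strand flips/duplicates, tissue expression with exact
  specificity targets, and QC-labelled reads.

The package is primarily a Python library (see `examples/`); a thin
`avirescue` command-line interface wraps the pipeline for shell use.

## Worked example

`examples/kaks_contrast.py` simulates two ortholog cohorts evolving at
different dN/dS and contrasts their NG86 estimates:

```
mean Ka/Ks, 'missing'-like cohort   (true omega 0.90): 0.865 (n=120)
mean Ka/Ks, genome-wide-like cohort (true omega 0.99): 0.960 (n=120)
Welch t = -3.82, two-sided p = 1.67e-04
```

Both cohorts sit below 1 (purifying selection) and the recovered-gene
cohort is significantly lower — the estimator recovers the simulated
ω values and the group contrast is detectable at this sample size.

`examples/recover_missing_genes.py` runs the pipeline end to end on 40
candidate genes across five species and prints the confidence bins:

```
   bin  count  percent
  high     22     55.0
medium     18     45.0
   low      0      0.0
absent      0      0.0

Median ortholog hit ratio: 1.000
```

Every candidate present in a species' transcripts is found there, so
no gene falls to *low* or *absent* — genes land in *absent* only when
they are truly lost in every species (they emit no transcripts at
all). The other examples cover QC/ORF extraction, GC composition and
tissue specificity.

A full pipeline run from the shell:

```bash
avirescue run-all --outdir run1 --seed 42
cat run1/report.md
```

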