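# Methods

This note documents the models, conventions and numerical choices
behind `avirescue`, and what the synthetic study system does and does
not establish about real data.

## The analysis in one paragraph

Candidate "missing" genes — genes annotated in other vertebrates but
absent from avian annotations — are searched for in de novo assembled
transcript sets, one per species. Transcripts pass whole-read QC and
redundancy collapse, the longest ORF per transcript is translated, and
each reference protein is aligned against the species' peptide set;
the best hit passing identity > 40% and E ≤ 1e-10 counts as a
recovery. Genes are then binned by how many species recovered them,
and the recovered sequences are characterised by completeness (OHR),
GC composition, tissue specificity (Yanai's τ) and selective pressure
(NG86 Ka/Ks against the reference).

## Read filter

A read is kept iff its length is ≥ `min_length` (default 70 bp) and
the fraction of bases with Phred quality below `quality_threshold`
(default Q30) is ≤ `max_low_quality_fraction` (default 5%). Filtering
is whole-read only (no trimming) and idempotent. FASTQ is Phred+33
only; other encodings are rejected.

## ORF extraction

All six frames are scanned. With `require_start` on (default for the
standalone API, following TransDecoder-like practice with a default
100-aa minimum), a candidate is a complete ATG-to-stop span; with it
off, maximal stop-free codon runs truncated at the sequence ends also
qualify — assembled fragments often lack the true start or stop, so
the pipeline default is `require_start=False` with a 30-aa minimum.

Candidates are ranked by nucleotide span with the stop codon counted
as part of the ORF; complete (stop-terminated) ORFs are preferred over
truncated runs of equal span, then the peptide string, then + strand,
then the smaller start coordinate. This ordering is invariant under
reverse-complementing the input — both orientations scan the same six
frames and the key does not depend on which strand is labelled “+”.
The completeness preference matters in practice: for a GC-rich CDS the
antisense strand often has no stop codons at all, so its truncated
full-length run would otherwise beat the genuine sense ORF (whose
peptide is one residue shorter than the antisense run) and the gene
would be reported as an unalignable antisense peptide. Coordinates are
0-based half-open internally and 1-based inclusive in written tables.

## Redundancy collapse

Greedy incremental clustering over transcripts sorted by descending
length (ties by id): a transcript joins the first cluster whose
representative contains an infix alignment of the *entire* shorter
sequence at identity ≥ 0.95 (edit-distance based, computed with
edlib's infix mode); otherwise it founds a cluster. Aligning the full
shorter sequence means its coverage is always 1.0, which satisfies the
0.8 minimum-coverage contract; the trade-off is that a sequence whose
ends diverge counts those ends as mismatches and may stay separate
where a local-alignment tool would merge. Word-filter heuristics of
the original clustering tools are intentionally not reproduced;
desk-scale inputs do not need them. Clustering is idempotent and maps
every input to exactly one representative.

## Homology search

Smith–Waterman with affine gaps (Gotoh), BLOSUM62, gap open 11 /
extend 1, where a gap of length L costs `11 + L·1`. Dynamic-
programming and traceback kernels are numba-compiled; traceback ties
prefer diagonal, then up, then left, and the maximal cell with the
smallest (i, j) starts the traceback, so results are deterministic.

Identity is the percentage of identical columns over *all* aligned
columns, gap columns included — a conservative denominator, stated
explicitly because BLAST's differs. E-values use the Karlin–Altschul
form `E = K·m·n·e^(−λS)` with the ungapped BLOSUM62 constants
(λ = 0.267, K = 0.041) applied to gapped scores; this preserves the
threshold behaviour of an E ≤ 1e-10 filter without reproducing BLAST's
exact statistics. In a best-hit search, `n` is the total residue count
of the species peptide set. Among passing alignments the highest score
wins; ties break by higher identity, longer alignment, then
lexicographically smaller subject id, making the result independent of
input order.

A practical floor follows from the E-value model: at ~50% identity a
peptide needs roughly 100 aligned residues to reach E ≤ 1e-10 against
a transcriptome-sized database, so very short genes are undetectable
under these filters no matter how real they are. This matches the
behaviour of the original screen and is a known limitation.

## Recovery classification and OHR

For each candidate gene the number of recovering species maps to a
bin: *high* = all species, *medium* = more than half but not all,
*low* = at least one but at most half, *absent* = none (for 5 species:
5 / 3–4 / 1–2 / 0). Percentages always use the actual candidate-list
length as denominator and are printed alongside it. OHR is the raw
ratio of the best recovered CDS length (the full extracted ORF of the
best-hit transcript, not the aligned span) to the reference CDS
length; it is not clamped, so values slightly above 1 occur when
in-frame UTR sequence extends the recovered ORF.

## Expression

RPKM = `counts·10⁹ / (library_size · length)`; TPM normalises
length-corrected counts to 10⁶ per tissue. Yanai's index
`τ = Σ(1 − vᵢ/v_max)/(N−1)` is computed on RPKM by default
(configurable to TPM); τ is scale-invariant, 0 iff uniform, 1 iff
single-tissue, undefined (reported missing) for all-zero genes. Ties
for the maximal tissue go to the first tissue in column order; in
enrichment tables tied maxima are split fractionally so per-set
fractions sum to 1. A guard warns when τ is computed over ≤ 10
tissues, where the index loses resolution. "Highly expressed in a
tissue" means value ≥ 3 × the mean over all tissues (boundary
inclusive, focal tissue included in the mean; both choices exposed).

## NG86 Ka/Ks

Peptides are aligned globally (Needleman–Wunsch, same scoring scheme)
and back-translated so gaps come in frame-preserving triplets;
stripping gaps recovers the inputs exactly. Per ungapped, stop-free
codon column: each position contributes the fraction of its three
single-base changes that are synonymous to S (stops count as
nonsynonymous), so S + N = 3 per codon; site counts are averaged over
the two sequences. Differences are averaged over all orderings of the
differing positions, skipping orderings that pass through a stop codon
and renormalising (if every ordering is blocked, all are used and
stop transitions count as nonsynonymous — a rare fallback). Both
proportions receive the Jukes–Cantor correction
`d = −(3/4)·ln(1 − (4/3)p)`; p ≥ 3/4 makes the rate undefined, Ks = 0
makes the ratio undefined, and both are reported as missing with a
reason rather than coerced to 0 or ∞. Group contrasts use Welch's
two-sided t-test over the defined ratios, with excluded counts
reported. This counting estimator replaces model-averaged
maximum-likelihood estimation; it is fully auditable against
brute-force enumeration and preserves group-contrast logic, but its
absolute values are not comparable to ML estimates at high divergence.

## Synthetic study system

The generator emulates the study conditions with known truth; all
randomness flows from one seed through named per-stage substreams, so
identical configurations are byte-reproducible.

* **Reference genes.** Per-gene GC targets come from a two-component
  normal mixture (defaults: means 46% and 60%, sds 3 and 5, weights
  0.35/0.65 — a bimodal, GC-rich-skewed distribution of the kind seen
  in avian missing genes). GC is steered by exponentially tilting
  codon choice, with the tilt solved per gene by bisection; a gene
  whose realised GC cannot land within ±5 points of target fails
  loudly, naming the gene. CDS lengths are gamma-distributed, clipped
  to 100–500 codons with mean 220 — scaled down from real protein
  lengths (median human CDS ≈ 430 codons) for runtime, but kept above
  the ~100-aa detection floor of the E-value filter, since
  shorter-than-real genes would make the synthetic screen artificially
  harder than the real one. Every CDS starts ATG, ends with a stop and
  has no internal stops.
* **Status.** Per (gene, species): lost with probability `p_lost`;
  otherwise hidden (present in transcripts, absent from the mock
  annotation) with probability `p_hidden`, else annotated. Lost genes
  emit no transcripts at all.
* **Divergence.** A proposal/acceptance codon process: random
  single-base proposals are accepted with probability 1 if synonymous
  and min(ω, 1) if nonsynonymous (for ω > 1 the weights become 1/ω
  and 1); proposals creating stops are rejected; start/stop codons are
  held fixed so ORFs stay intact. `divergence` is the expected number
  of accepted substitutions per evolvable nucleotide site. Accepted
  synonymous/nonsynonymous counts are recorded per gene, making the
  realised ω auditable. Because proposals are uniform, the
  instantaneous nonsynonymous/synonymous rate ratio equals ω exactly
  in NG86's site decomposition; the small residual bias (≈ 4%) comes
  from stop-adjacent mutants being counted as nonsynonymous sites but
  never substituted.
* **Transcripts.** By default every non-lost gene yields one
  full-length transcript (the default recovery scenario assumes
  complete assemblies); fragmentation draws a contiguous CDS window
  with coverage uniform on [`min_coverage`, 1]. Optional decorations:
  UTR-like random flanks (default 30% of transcripts, 20–150 nt per
  side, 45% GC), reverse-complementation (30%), and same-orientation
  near-duplicates (10%, trimmed up to 10%) to exercise strand handling
  and collapse. True coverage is recorded per transcript and per
  (gene, species).
* **Expression.** Each gene's noise-free profile has value 1 in one
  random maximal tissue and `1 − τ_target` elsewhere, so its
  noise-free Yanai index equals the target exactly (and τ = 1 genes
  have exactly one nonzero tissue even after sampling). Counts are
  negative-binomial around abundance-scaled profiles (log-normal
  abundances, dispersion 0.05 by default; 0 gives Poisson),
  column-rescaled so expected tissue totals equal the library sizes
  (10⁶ by default, 12 tissues). Parameter-recovery experiments for τ
  use dispersion 0: under a fixed overdispersion the index estimate is
  biased upward for broadly expressed genes (the max statistic of
  overdispersed counts) at any depth, so the sampling-noise-limited
  regime is the meaningful convergence check. Measured mean absolute
  error there is ≈ 0.015 over 500 genes.
* **Reads.** Phred+33 reads with labelled failure classes: a
  configurable fraction shorter than 70 bp and a fraction with 10% of
  bases at Q20 (> 5% below Q30); the rest are full-length Q40. Truth
  labels let the read filter be checked read-for-read.

### What the synthetic system does not model

No indels in evolution (substitutions only), no isoform structure, no
misassembly chimeras, no read-level quantification noise (counts are
generated directly), and UTRs are random sequence rather than real
regulatory sequence. Passing the recovery experiments therefore shows
the pipeline's logic and estimators are correct under controlled
divergence, fragmentation and expression noise — not that real
assemblies of real libraries reach the same recovery rates.

## Problem sizes and determinism

Default experiment sizes were chosen to keep any full run in tens of
seconds on one core: 100-gene × 5-species recovery scenarios, 200
ortholog pairs per ω arm, 500 genes × 12 tissues for τ recovery, and
oracle checks at 100 random instances each. Alignment kernels are
exact (no heuristics), so problem size affects only runtime, never the
optimum. All stochastic components take explicit seeds; identical
(config, seed) reproduce byte-identical artifacts and manifest counts.

## Known limitations

* Genes shorter than ~100 aa are undetectable under the stated
  identity/E-value filters (see Homology search).
* The E-value model is approximate (ungapped constants on gapped
  scores); absolute E-values should not be compared to BLAST output,
  only the thresholded behaviour.
* NG86 saturates at high divergence (undefined beyond p ≥ 3/4); group
  means exclude undefined ratios and report how many were dropped.
* Collapse identity is measured over the full shorter sequence
  (effective coverage 1.0), slightly stricter than coverage-0.8 local
  clustering for sequences with divergent ends.
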