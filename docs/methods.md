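# Methods

This note documents the models, algorithmic choices and default parameters
behind `snmcpipe`, what the synthetic data does and does not emulate, and the
known limitations.

## The simulated library chemistry

A post-bisulfite adapter-tagged (PBAT) single-cell library starts from a
bisulfite-converted single-stranded template, which is C-depleted: an
unmethylated cytosine is read as T with probability `conversion_rate`
(default 0.995), while methylated cytosines are protected. A random primer
carrying the sequencing adapter and an 8-nt in-line barcode synthesises the
complement of that template, and the Adaptase reaction tags the 3' end of
the synthesised strand with a short low-complexity tail. Consequently:

* **R1** reads the synthesised strand: barcode first, then genomic sequence
  with the G→A signature (the complement of a C-depleted strand is
  G-depleted).
* **R2** reads back the template sense: the complement of the Adaptase tail
  first, then C-depleted (C→T signature) genomic sequence. With a ~42% GC
  genome and mostly unmethylated cytosines, only ~1–2% of R2 genomic bases
  are expected to read as C — which is why a contaminated tail is visible as
  an elevated C frequency at R2 starts.

Both original genomic strands are sampled with equal probability; each
contributes its own template.

### Tail model

Tail length is geometric with mean `tail_mean` (default 8 bp), truncated at
`tail_max` (default 50 bp) by resampling — the maximum-entropy choice given
only a mean and a hard cap. The truncation pulls the realised mean to
~7.87 bp. Tail bases are drawn from `tail_alphabet_weights` expressed in R2
read space. The default is A/G (equal weights), i.e. C/T on the tailed
strand: a C-free R2 prefix is required for the clean-versus-contaminated C
contrast to exist at all, and among C-free two-letter alphabets A/G minimises
the overlap with post-bisulfite genomic sequence (~50% A+G vs ~71% G+T),
which halves the tail detector's overshoot. Under dNTP-carryover
contamination the alphabet becomes uniform four-letter
(`LibraryParams.contaminated()`); tail lengths are unchanged.

### Other artifacts

* **Adapter dimers**: a fraction `dimer_fraction` (default 0.06) of pairs
  carry a zero-length insert and read straight into adapter sequence. The
  primer chemistry behind dimer formation is not modelled; the fraction is a
  direct parameter.
* **PCR duplicates**: with probability `duplicate_rate` (default 0.05) a
  pair re-emits a previously synthesised molecule — same coordinates, same
  conversion pattern, same tail — with independent sequencing errors.
* **Spike-in**: reads are drawn from the fully unmethylated lambda contig
  with probability `lambda_spike_fraction` (default 0.01).
* **Sequencing error**: uniform substitutions at `seq_error_rate` (default
  0.001), applied after conversion. No indels and no quality-score model
  (qualities are written as a constant) — the aligner is correspondingly
  ungapped.

## The methylome model

Each cell type has a global CH level (`mch_level`), CG levels per region
class (`mcg_default` = 0.8 genome-wide, `mcg_cgi` = 0.25 inside CpG
islands), and per-gene multipliers on gene-body mCH — the cell-type
signature, reflecting the anticorrelation of gene-body CH methylation with
expression. On top sits a regional landscape: a lognormal multiplier (mean
1, log-sd `regional_sigma` = 0.5) per 2 kb window, shared by all cell
types, emulating the several-fold regional variability of real CH
methylation. The landscape is what gives bin-level profiles genuine
between-bin variance, so that replicate-consistency correlations measure
signal rather than noise; because it is shared across types and the
embedding centres each bin, it does not influence clustering. Every
cytosine in every cell is then an independent Bernoulli draw at its
context-, region- and type-appropriate level; the lambda contig is always
fully unmethylated.

The bundled model has three cortical stand-ins (global mCH 0.03 / 0.04 /
0.06) differing at eleven 4-kb gene bodies. The annotation markers follow
the layer 2/3 excitatory signature: Cux1 and Satb2 multipliers lowest in
the L23 type, Rorb highest. What the synthetic data does *not* emulate:
real genome scale and repeat structure, indels and quality decay,
context-specific conversion biases, chromatin-driven coverage biases, or
doublets. Passing tests therefore demonstrate the correctness of the
algorithms under the stated generative model, not performance on real
libraries.

## Preprocessing

* **Demultiplexing** assigns an R1 prefix to the unique barcode within
  `max_mismatch` (default 1); the default 8 barcodes have pairwise Hamming
  distance ≥ 5, so assignment is unambiguous by construction. Together with
  768 dual-index pairs this yields 6144 cell labels.
* **Tail detection** is a first-exit rule: the detected tail is the longest
  R2 prefix consisting solely of tail-alphabet bases, capped at `tail_max`.
  Past the true boundary the detector extends only while genomic bases
  happen to fall in the alphabet, so the per-read overshoot is geometric
  with mean `q/(1-q)` (q = in-alphabet rate of genomic sequence, ~0.5 for
  A/G). A cumulative-90%-in-alphabet rule was considered and rejected: it
  can bridge isolated out-of-alphabet bases and extends several bases past
  the boundary on average, biasing the recovered mean tail length beyond
  recovery tolerances. The batch-level estimator `tail_length_summary`
  removes the first-exit bias analytically by subtracting `q̂/(1-q̂)`, with
  q̂ measured from read positions beyond `tail_max` (never tail). At the
  default error rate the chance of an error truncating a tail early is
  ~0.1% per read and is ignored.
* **Trimming order**: tail removal, adapter removal (exact 12-mer seed,
  then suffix overlap ≥ 5), then the historical fixed end trims (16 bp at
  both ends of both mates; `r2_extra_5p` available for sweeps). A pair
  whose trimmed R1 is shorter than `min_insert` (default 30 bp) is
  classified `dimer_or_short`; R1 is the insert proxy because it carries no
  tail. The 30 bp cutoff is a declared convention — the field quantifies
  "adapter dimer and short insert" without a standard threshold.
* **Composition diagnostics**: exact per-position base frequencies;
  the anomaly flag fires when the max C frequency over the first 10 R2
  positions exceeds the post-bisulfite expectation by more than 0.02 — a
  margin that cleanly separates the contaminated (~25% C at R2 starts)
  from the clean (~1–2%) regime.

## Alignment

Exact k-mer seeding (k = 16, every 5th offset plus the final one) over two
converted reference frames (Watson C→T and Watson G→A), ungapped extension,
score = matches − mismatches, mismatch fraction ≤ 0.1. Each read is tried in
the orientations its mate chemistry allows (R2: C→T forward / reverse;
R1: G→A mirrored). MAPQ is `min(60, 2*(best − second_best))` with
`second_best = 0` for a unique locus; exact ties give MAPQ 0 and are
removed by the strict `MAPQ > 10` filter. Clonal reads — identical
(cell, contig, start, frame) — collapse to the highest-scoring
representative. The MAPQ formula and mismatch threshold are this package's
own conventions for a desk-scale aligner; only the `MAPQ > 10` filter
semantics follow standard practice. Reads whose implied alignment would
run past a contig end are unmapped rather than clipped.

## Methylation calling

CT-frame hits report Watson cytosines (read C = methylated basecall, read T
= unmethylated; other bases ignored), GA-frame hits the mirror image on
Crick cytosines, reported on the `-` strand at the same coordinate.
Overlapping mates are resolved by keeping R1's basecall. The allc dialect
has 7 columns; the `methylated` flag is a one-sided binomial test of mc/cov
against the conversion-failure rate at p < 0.01 and is not used downstream.
Reported levels are raw — no conversion-failure correction — with
`correct_for_conversion_failure` available as a utility. Global levels and
clustering exclude the spike-in contig, which is a conversion control, not
methylome signal.

## Library complexity

The duplication histogram counts read start loci (cell, contig, start,
frame) observed exactly j times, so `Σ j·n_j` equals retained reads. The
Good–Toulmin series predicts new distinct loci at fold t; for t − 1 > 1 the
alternating series is summed by Euler transformation (iterated averaging of
partial sums) — a classical tame replacement for rational-function
acceleration, validated against the analytic Poisson expectation
`G(1 − e^(−2λ))` rather than against any external binary. Estimates are
clamped to [observed, genome capacity] and curves are forced monotone. The
default reference depth (50 million pairs, bound 5e9, step 1e7) matches
standard practice; at desk-scale read counts the implied fold change is
astronomically outside the estimator's validity and the prediction simply
saturates at genome capacity — the meaningful regime (folds of a few) is
what the oracle tests exercise. The fraction-of-genome statistic converts
distinct loci via the mean retained read length.

## Clustering

Bins are genome-anchored half-open tiles (default 100 kb; the bundled demo
uses 5 kb because its genome is 120 kb). The coverage filter keeps a bin
iff strictly more than `min_cell_fraction` (0.975) of cells have strictly
more than `min_basecalls` (100) CH basecalls in it. Ratios are divided by
each cell's global mCH (cells with non-positive global mCH are excluded
with a warning); uncovered entries in kept bins are imputed with the
across-cell bin mean, the choice that adds no between-cell signal to PCA.
Columns are centred but not scaled; PCA uses the deterministic full SVD and
returns min(n_pcs, rank) components (default 150). Clustering is Ward on
Euclidean distances in PC space; k may be supplied (the recovery analyses
use k = 3) or defaults to the largest merge-height gap, with an all-merges-
at-zero tree collapsing to one cluster. Annotation computes pooled
gene-body mCH per cluster per marker gene and labels a cluster when every
"low" gene is strictly below and every "high" gene strictly above the
across-cluster median for that gene; several qualifying clusters are all
labelled and flagged ambiguous. Cross-dataset correlation pools mc/cov per
interval per dataset and reports Pearson r over intervals covered in both
(refusing fewer than 3).

## Problem sizes and reproducibility

The bundled study runs 30 cells x 500 pairs on a 140 kb genome (two 60 kb
autosome stand-ins + 20 kb lambda) — sizes chosen so every stage, including
alignment, runs in seconds while leaving hundreds of CH basecalls per 5 kb
bin, comfortably above the coverage filter. Replicate-correlation analyses
use 2 kb bins: with ~120 bp of CH-site content per kilobase, smaller bins
on this genome are dominated by binomial truth-draw noise and bound the
attainable correlation regardless of sequencing depth. All randomness flows
from numpy Generators seeded from a single global seed (per-stage seeds are
derived by stable hashing); FASTQ output is gzipped with a zeroed timestamp
so reruns are byte-identical.

## Known limitations

* Ungapped alignment only; indel-containing reads (not simulated) would be
  lost or mis-scored.
* The aligner is exhaustive-verified only at desk scale; its index is an
  in-memory dict, not suitable for mammalian genomes.
* Complexity extrapolation far beyond a few-fold depth increase saturates
  by design rather than estimating meaningfully.
* Conversion-failure inflation (~0.005) is left in reported levels; at very
  low mCH it compresses contrasts between cell types.
* Dual-index pairs are consumed as labels only; index hopping is not
  modelled.
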