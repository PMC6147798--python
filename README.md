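# snmcpipe

A desk-scale, fully testable computational stack for single-nucleus DNA
methylome sequencing (post-bisulfite adapter-tagged, PBAT, libraries with
in-line barcode multiplexing). It covers the whole path from raw paired-end reads to annotated
cell types — and, because real single-cell bisulfite data is bulky and slow to
process, it ships a first-class simulator that reproduces the protocol's
characteristic artifact chemistry so that every stage can be verified against
ground truth on a laptop.

**Who it is for.** Method developers and students who want a transparent,
inspectable implementation of the single-cell methylome pipeline: how
bisulfite-converted reads are demultiplexed, trimmed, aligned in three-letter
space, turned into per-cytosine methylation calls (allc tables), summarised
into per-cell QC, and clustered into cell types from genome-bin mCH profiles.

## What it implements

* **Simulation** (`snmcpipe.synthio`): a small genome with CpG islands, gene
  models and an unmethylated lambda spike-in contig; per-cell binary
  methylation truth drawn from a cell-type methylome model (CG vs CH context,
  CGI-specific mCG, gene-body mCH multipliers, a regional mCH landscape);
  paired-end reads carrying an 8-nt in-line barcode at R1 starts, a
  low-complexity Adaptase tail at R2 starts (geometric length, mean 8 bp,
  capped at 50 bp; four-letter alphabet under dNTP-carryover contamination),
  adapter-dimer pairs, PCR duplicates and bisulfite conversion with
  configurable per-cytosine efficiency (default 0.995 for unmethylated C).
* **Preprocessing** (`snmcpipe.preprocess`): barcode demultiplexing with
  Hamming-distance tolerance (8 barcodes x 768 dual-index pairs = 6144 cell
  labels), adapter/tail/end trimming with adapter-dimer classification, and
  per-position base-composition diagnostics against the post-bisulfite
  expectation `E[C] = f_C (m̄ + (1 - m̄)(1 - c))`, which flags the elevated-C
  anomaly that contaminated Adaptase tails produce at R2 starts.
* **Alignment** (`snmcpipe.bsalign`): a three-letter (bisulfite-aware)
  seed-and-extend aligner over C→T and G→A converted reference frames with
  `MAPQ = min(60, 2*(best - second_best))`, the standard strict `MAPQ > 10`
  filter, and clonal-read collapse.
* **Methylation calling** (`snmcpipe.mcall`): per-cytosine allc-style tables
  (position, strand, trinucleotide context, methylated/total basecalls),
  conversion-rate estimation from the lambda spike-in
  (`rate = 1 - Σmc/Σcov`), and global mCG/mCH per cell.
* **QC** (`snmcpipe.libqc`): per-cell QC records, Good–Toulmin library
  complexity extrapolation from the duplication histogram
  (`Δ(t) = Σ_j (-1)^(j+1) (t-1)^j n_j`, Euler-transformed for t > 2),
  coverage-uniformity and CGI-enrichment statistics, and Welch t-tests for
  protocol comparisons.
* **Clustering** (`snmcpipe.mcluster`): cell x genome-bin mCH matrices
  (default 100 kb bins), the strict coverage filter (>100 basecalls in >97.5%
  of cells), per-cell global-mCH normalisation, PCA (top 150 components) +
  Ward hierarchical clustering, marker-gene annotation (layer 2/3 excitatory
  neurons: low gene-body mCH at Cux1 and Satb2, high at Rorb) and
  cross-dataset interval correlations.

## Worked example

Run the bundled synthetic study (30 cells, three neuronal cell types, two
60 kb autosome stand-ins plus a 20 kb lambda spike-in contig; 5 kb bins fit
this genome):

```python
from snmcpipe.config import PipelineConfig
from snmcpipe.pipeline import run_pipeline

cfg = PipelineConfig.from_dict({"seed": 7, "cluster": {"bin_size": 5000, "k": 3}})
res = run_pipeline(cfg, "demo_out", until="cluster")
print(res.qc_table.head(4))
print(res.assignment.frame().head(4))
print(res.assignment.marker_evidence)
```

prints (abridged):

```
   cell  assigned_pairs  dimer_fraction  combined_mapping_rate  conversion_rate    mcg    mch
L23_000             500           0.056                    1.0           1.0000 0.6869 0.0329
L23_001             500           0.066                    1.0           0.9852 0.7055 0.0315
L23_002             500           0.060                    1.0           1.0000 0.6922 0.0311
L23_003             500           0.048                    1.0           1.0000 0.7309 0.0384

   cell  cluster      annotation
L23_000        1 L2/3 excitatory
L23_001        1 L2/3 excitatory
L23_002        1 L2/3 excitatory
L23_003        1 L2/3 excitatory

marker evidence (gene-body mCH per cluster):
           Cux1    Rorb   Satb2
cluster                        
1        0.0139  0.0892  0.0119
2        0.0659  0.0567  0.0876
3        0.0671  0.0221  0.0173
```

Reading this: each cell was simulated with a 6% adapter-dimer rate and the
measured `dimer_fraction` recovers it; `conversion_rate` is estimated from
the lambda spike-in (simulated at 0.995); `mch` is the global CH methylation
level that separates the three cell types (~0.03 / 0.04 / 0.06). Clustering
on normalised 5 kb-bin mCH recovers the three simulated types exactly, and
cluster 1 is annotated "L2/3 excitatory" because its gene-body mCH is lowest
at Cux1 and Satb2 and highest at Rorb — matching the simulated truth.

The same pipeline is available from the shell:

```bash
snmcpipe run --seed 7 --out demo_out            # full pipeline, defaults
snmcpipe simulate --out sim && snmcpipe demux --r1 sim/fastq/P001_R1.fastq.gz \
    --r2 sim/fastq/P001_R2.fastq.gz --out demuxed
```

## Layout

```
src/snmcpipe/      synthio, preprocess, bsalign, mcall, libqc, mcluster,
                   config, pipeline, cli, genome (containers + IO)
tests/             pytest suite (unit, property and end-to-end tests)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```
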