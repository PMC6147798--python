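"""End-to-end orchestration: simulate -> demux -> trim -> align -> call ->
qc -> cluster, driven by one :class:`~snmcpipe.config.PipelineConfig`.

Any stage prefix is selectable; outputs are written as plain-text standard
formats (FASTA, gzipped FASTQ, BED, SAM, allc/QC TSV) plus a JSON run
manifest recording seeds, parameter hash and library versions. Reruns with
the same config are byte-identical through alignment and deterministic
thereafter.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bsalign import ConvertedIndex, align_pairs, filter_alignments, write_sam
from .config import PipelineConfig
from .genome import ReadPair, write_bed, write_fastq_pair
from .libqc import (
    assemble_qc,
    duplication_histogram,
    extrapolate_complexity,
)
from .mcall import call_methylation, estimate_conversion, global_levels, write_allc
from .mcluster import (
    annotate_clusters,
    bin_mch,
    cluster_cells,
    filter_bins,
    normalize_and_embed,
)
from .preprocess import BarcodeSet, TrimPolicy, demultiplex, trim_pairs
from .synthio import (
    LibraryParams,
    default_genome_spec,
    default_methylome_model,
    simulate_genome,
    simulate_methylome,
    simulate_run,
)

STAGES = ["simulate", "demux", "trim", "align", "call", "qc", "cluster"]

log = logging.getLogger("snmcpipe")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    syn: object = None
    truth: object = None
    cell_barcode: dict = field(default_factory=dict)
    plates: dict = field(default_factory=dict)           # plate -> multiplexed pairs
    truth_table: pd.DataFrame | None = None
    cell_pairs: dict = field(default_factory=dict)       # cell -> raw assigned pairs
    trimmed: dict = field(default_factory=dict)          # cell -> kept pairs
    trim_reports: dict = field(default_factory=dict)
    input_pairs: dict = field(default_factory=dict)
    map_counts: dict = field(default_factory=dict)
    filtered_hits: dict = field(default_factory=dict)
    prefilter_hits: dict = field(default_factory=dict)
    allc: dict = field(default_factory=dict)
    conversion: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)
    qc_table: pd.DataFrame | None = None
    assignment: object = None
    manifest: dict = field(default_factory=dict)


def _library_params(cfg: PipelineConfig) -> LibraryParams:
    s = cfg.simulate
    kw = dict(
        conversion_rate=s.conversion_rate,
        read_length=s.read_length,
        insert_mean=s.insert_mean,
        insert_sd=s.insert_sd,
        dimer_fraction=s.dimer_fraction,
        tail_mean=s.tail_mean,
        tail_max=s.tail_max,
        duplicate_rate=s.duplicate_rate,
        seq_error_rate=s.seq_error_rate,
        lambda_spike_fraction=s.lambda_spike_fraction,
    )
    return LibraryParams.contaminated(**kw) if s.contaminated else LibraryParams(**kw)


def _trim_policy(cfg: PipelineConfig) -> TrimPolicy:
    t = cfg.trim
    return TrimPolicy(
        fixed_5p_r1=t.fixed_5p_r1, fixed_3p_r1=t.fixed_3p_r1,
        fixed_5p_r2=t.fixed_5p_r2, fixed_3p_r2=t.fixed_3p_r2,
        r2_extra_5p=t.r2_extra_5p, min_insert=t.min_insert,
        tail_detect=t.tail_detect, tail_max=t.tail_max,
    )


def run_pipeline(
    config: PipelineConfig, outdir, until: str = "cluster"
) -> PipelineResult:
    """Run the pipeline up to (and including) the ``until`` stage."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    last = STAGES.index(until)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    res = PipelineResult(config, outdir)
    res.manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages_run": [],
    }

    for stage in STAGES[: last + 1]:
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, res)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, str(exc)) from exc
        res.manifest["stages_run"].append(stage)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
    return res


def _stage_simulate(cfg: PipelineConfig, res: PipelineResult) -> None:
    seed = cfg.stage_seed("simulate")
    spec = default_genome_spec(seed=seed)
    syn = simulate_genome(spec)
    model = default_methylome_model()
    truth = simulate_methylome(syn, model, cfg.simulate.n_cells_per_type, seed=seed + 1)
    plates, truth_table, cell_barcode = simulate_run(
        syn, truth, _library_params(cfg), cfg.simulate.n_pairs_per_cell, seed=seed + 2
    )
    res.syn, res.truth = syn, truth
    res.cell_barcode = cell_barcode
    res.truth_table = truth_table
    res.plates = plates

    syn.genome.to_fasta(res.outdir / "genome.fa")
    write_bed(syn.cgi_intervals, res.outdir / "cgi.bed")
    write_bed(syn.gene_models, res.outdir / "genes.bed")
    truth_table.to_csv(res.outdir / "truth_reads.tsv", sep="\t", index=False)
    fq = res.outdir / "fastq"
    fq.mkdir(exist_ok=True)
    for plate, pairs in plates.items():
        write_fastq_pair(pairs, fq / f"{plate}_R1.fastq.gz", fq / f"{plate}_R2.fastq.gz")


def _stage_demux(cfg: PipelineConfig, res: PipelineResult) -> None:
    bs = BarcodeSet()
    bc_cells = {
        (plate, bc): cell
        for cell, bc in res.cell_barcode.items()
        for plate in [f"P{res.truth.cells.index(cell) // len(bs.barcodes) + 1:03d}"]
    }
    counts_rows = []
    for plate, pairs in res.plates.items():
        by_bc, counts = demultiplex(pairs, bs)
        for bc, cell_pairs in by_bc.items():
            cell = bc_cells.get((plate, bc))
            if cell is None:
                continue
            res.cell_pairs[cell] = cell_pairs
            res.input_pairs[cell] = len(pairs)
        counts_rows.append(counts.rename(plate))
    pd.DataFrame(counts_rows).to_csv(res.outdir / "demux_counts.tsv", sep="\t")


def _stage_trim(cfg: PipelineConfig, res: PipelineResult) -> None:
    policy = _trim_policy(cfg)
    for cell, pairs in res.cell_pairs.items():
        kept, report = trim_pairs(pairs, policy)
        res.trimmed[cell] = kept
        res.trim_reports[cell] = report


def _stage_align(cfg: PipelineConfig, res: PipelineResult) -> None:
    index = ConvertedIndex(res.syn.genome, k=cfg.align.k)
    all_filtered = []
    for cell, pairs in res.trimmed.items():
        hits, counts = align_pairs(
            pairs, index, cell=cell,
            seed_step=cfg.align.seed_step,
            max_mismatch_frac=cfg.align.max_mismatch_frac,
        )
        res.map_counts[cell] = counts
        res.prefilter_hits[cell] = [h for h in hits if h.mapq > cfg.align.mapq_min]
        res.filtered_hits[cell] = filter_alignments(hits, mapq_min=cfg.align.mapq_min)
        all_filtered.extend(res.filtered_hits[cell])
    write_sam(all_filtered, res.syn.genome, res.outdir / "filtered.sam")


def _stage_call(cfg: PipelineConfig, res: PipelineResult) -> None:
    catalog = res.syn.catalog
    all_hits = [h for hits in res.filtered_hits.values() for h in hits]
    res.allc = call_methylation(
        all_hits, res.syn.genome, catalog,
        conversion_rate=cfg.simulate.conversion_rate,
    )
    allc_dir = res.outdir / "allc"
    allc_dir.mkdir(exist_ok=True)
    lam = res.syn.genome.lambda_contig
    for cell, allc in res.allc.items():
        write_allc(allc, allc_dir / f"allc_{cell}.tsv")
        res.conversion[cell] = estimate_conversion(allc, lam)
        res.levels[cell] = global_levels(allc, exclude_contigs=(lam,))


def _stage_qc(cfg: PipelineConfig, res: PipelineResult) -> None:
    complexity = {}
    genome_size = sum(
        l for n, l in res.syn.genome.lengths.items()
        if n != res.syn.genome.lambda_contig
    )
    for cell, hits in res.prefilter_hits.items():
        if not hits:
            continue
        hist = duplication_histogram(hits)
        span = float(np.mean([h.length for h in hits]))
        target = max(float(cfg.qc.reference_depth_pairs), float(hist.total_reads))
        complexity[cell] = extrapolate_complexity(
            hist, target, genome_size=genome_size, read_span=span
        )
    cells = list(res.truth.cells)
    res.qc_table = assemble_qc(
        cells,
        demux_counts={c: len(p) for c, p in res.cell_pairs.items()},
        input_pairs=res.input_pairs,
        trim_reports=res.trim_reports,
        map_counts=res.map_counts,
        retained={c: len(h) for c, h in res.filtered_hits.items()},
        conversion=res.conversion,
        levels=res.levels,
        complexity=complexity,
    )
    res.qc_table.to_csv(res.outdir / "qc.tsv", sep="\t", index=False)


def _stage_cluster(cfg: PipelineConfig, res: PipelineResult) -> None:
    cc = cfg.cluster
    bm = bin_mch(res.allc, res.syn.genome, bin_size=cc.bin_size)
    bm = filter_bins(bm, cc.min_basecalls, cc.min_cell_fraction)
    gmch = {c: res.levels[c].mch for c in res.allc if c in res.levels}
    emb = normalize_and_embed(bm, gmch, n_pcs=cc.n_pcs)
    assignment = cluster_cells(emb, k=cc.k)
    assignment = annotate_clusters(assignment, res.allc, res.syn.gene_models)
    res.assignment = assignment
    emb.frame().to_csv(res.outdir / "embedding.tsv", sep="\t")
    assignment.frame().to_csv(res.outdir / "clusters.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "demux": _stage_demux,
    "trim": _stage_trim,
    "align": _stage_align,
    "call": _stage_call,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
}
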