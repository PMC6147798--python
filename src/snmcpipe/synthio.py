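"""Synthetic single-nucleus bisulfite libraries with PBAT artifact chemistry.

This module generates everything the rest of the pipeline consumes, plus the
ground truth needed to verify it: a small genome with CpG islands and gene
models, per-cell binary methylation states drawn from a cell-type methylome
model, and paired-end reads that carry the characteristic artifacts of
post-bisulfite adapter tagging:

* an 8-nt in-line barcode at the R1 5' end (embedded in the random primer);
* a low-complexity Adaptase tail at the R2 5' end, geometric in length
  (mean ``tail_mean``, truncated at ``tail_max``) over a two-letter alphabet,
  switching to a four-letter alphabet under dNTP carryover contamination;
* adapter-dimer pairs (zero-length insert reading straight into adapter);
* PCR duplicates that copy a previous molecule's coordinates, tail and
  conversion pattern;
* a fully unmethylated lambda spike-in contig for conversion-rate estimation.

Strand chemistry: the bisulfite-converted template is C-depleted. The random
primer synthesises its complement, which R1 reads (G->A signature); R2 reads
back the template sense (C->T signature) and therefore begins with the
complement of the Adaptase tail. ``tail_alphabet_weights`` are expressed in
R2 read space (default A/G, i.e. C/T on the tailed strand).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqops import A, C, G, T, array_to_seq, revcomp_array, seq_to_array
from .genome import (
    ContigCatalog,
    CytosineCatalog,
    Genome,
    ReadPair,
    build_cytosine_catalog,
    interval_mask,
    make_intervals,
    validate_intervals,
)

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default 8-nt in-line barcodes, pairwise Hamming distance >= 5.
DEFAULT_BARCODES = (
    "GCTAAAGA",
    "CAATTACA",
    "TAACATAC",
    "ACGTCAGC",
    "TGTTGGCC",
    "ATCGCTTA",
    "GTAAGTGT",
    "GTCCACCC",
)

BARCODE_LENGTH = 8

# Read-through adapter sequences (Illumina TruSeq-style), as seen at read 3'
# ends when the insert is shorter than the read.
ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

#: Marker-gene stand-ins used by the default methylome model and the
#: cell-type annotation rule (low gene-body mCH at Cux1/Satb2, high at Rorb
#: identifies layer 2/3 excitatory neurons).
MARKER_GENES = ("Cux1", "Satb2", "Rorb")


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Parameters of the synthetic genome.

    ``cgi_intervals`` get an elevated GC fraction and an explicit excess of CG
    dinucleotides over the genomic background; ``gene_models`` only annotate
    coordinates (sequence composition is background).
    """

    contigs: list[tuple[str, int]]
    gc_fraction: float = 0.42
    cgi_intervals: pd.DataFrame | None = None
    gene_models: pd.DataFrame | None = None
    lambda_contig: str | None = None
    seed: int = 0
    cgi_cg_rate: float = 0.08
    cgi_gc_fraction: float = 0.60
    min_contig_length: int = 10_000

    def __post_init__(self):
        if self.cgi_intervals is None:
            self.cgi_intervals = make_intervals([])
        if self.gene_models is None:
            self.gene_models = make_intervals([], extra_cols={"marker": []})

    def validate(self) -> None:
        if not self.contigs:
            raise ValueError("GenomeSpec needs at least one contig")
        for name, length in self.contigs:
            if length < self.min_contig_length:
                raise ValueError(
                    f"contig {name!r} length {length} < {self.min_contig_length}"
                )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        fake = Genome({n: "N" * l for n, l in self.contigs})
        validate_intervals(self.cgi_intervals, fake, what="CGI interval")
        validate_intervals(self.gene_models, fake, what="gene model")


@dataclass
class SyntheticGenome:
    """A simulated genome plus its annotation tracks."""

    genome: Genome
    cgi_intervals: pd.DataFrame
    gene_models: pd.DataFrame
    spec: GenomeSpec
    catalog: CytosineCatalog = field(default=None, repr=False)

    def __post_init__(self):
        if self.catalog is None:
            self.catalog = build_cytosine_catalog(self.genome)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_CODES[rng.choice(4, size=n, p=p)]


def simulate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate the genome sequence; deterministic for a fixed spec seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, str] = {}
    for name, length in spec.contigs:
        arr = _random_bases(rng, length, spec.gc_fraction)
        for row in spec.cgi_intervals.itertuples(index=False):
            if row.contig != name:
                continue
            i = row.start
            while i < row.end:
                if i + 1 < row.end and rng.random() < spec.cgi_cg_rate:
                    arr[i], arr[i + 1] = C, G
                    i += 2
                else:
                    arr[i] = _random_bases(rng, 1, spec.cgi_gc_fraction)[0]
                    i += 1
        contigs[name] = array_to_seq(arr)
    genome = Genome(contigs, lambda_contig=spec.lambda_contig)
    syn = SyntheticGenome(genome, spec.cgi_intervals, spec.gene_models, spec)
    if len(spec.cgi_intervals) and spec.gc_fraction > 0:
        inside, outside = cg_density_contrast(syn)
        if not inside > outside:
            raise RuntimeError(
                f"CGI CG density {inside:.4f} not above background {outside:.4f}; "
                "increase cgi_cg_rate"
            )
    return syn


def cg_density_contrast(syn: SyntheticGenome) -> tuple[float, float]:
    """CG-dinucleotide density inside vs outside CGI intervals."""
    n_in = n_out = len_in = len_out = 0
    for name in syn.genome.genomic_names():
        arr = syn.genome.arr(name)
        is_cg = (arr[:-1] == C) & (arr[1:] == G)
        mask = interval_mask(len(arr), syn.cgi_intervals, name)[:-1]
        n_in += int(is_cg[mask].sum())
        n_out += int(is_cg[~mask].sum())
        len_in += int(mask.sum())
        len_out += int((~mask).sum())
    return (n_in / max(len_in, 1), n_out / max(len_out, 1))


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """The bundled study genome: two 60 kb autosome stand-ins + 20 kb lambda."""
    cgis = make_intervals(
        [("chr1", s, s + 1000, f"CGI_chr1_{i}") for i, s in enumerate(range(5_000, 60_000, 15_000))]
        + [("chr2", s, s + 1000, f"CGI_chr2_{i}") for i, s in enumerate(range(7_000, 60_000, 15_000))]
    )
    genes = make_intervals(
        [
            ("chr1", 8_000, 12_000, "Cux1"),
            ("chr1", 20_000, 24_000, "Satb2"),
            ("chr1", 32_000, 36_000, "GeneA"),
            ("chr1", 40_000, 44_000, "GeneB"),
            ("chr1", 48_000, 52_000, "GeneC"),
            ("chr1", 54_000, 58_000, "GeneD"),
            ("chr2", 8_000, 12_000, "Rorb"),
            ("chr2", 20_000, 24_000, "GeneE"),
            ("chr2", 32_000, 36_000, "GeneF"),
            ("chr2", 40_000, 44_000, "GeneG"),
            ("chr2", 48_000, 52_000, "GeneH"),
        ],
    )
    genes["marker"] = genes["name"].isin(MARKER_GENES)
    return GenomeSpec(
        contigs=[("chr1", 60_000), ("chr2", 60_000), ("chrL", 20_000)],
        gc_fraction=0.42,
        cgi_intervals=cgis,
        gene_models=genes,
        lambda_contig="chrL",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Methylome model and per-cell truth
# ---------------------------------------------------------------------------

@dataclass
class CellTypeMethylome:
    """Methylation levels of one cell type.

    ``mcg_default``/``mcg_cgi`` are per-region-class CG methylation levels;
    ``mch_level`` is the global CH level; ``gene_body_mch`` maps gene name to
    a multiplier applied to ``mch_level`` inside the gene body (the cell-type
    signature: gene-body mCH anticorrelates with expression).
    """

    mch_level: float
    mcg_default: float = 0.8
    mcg_cgi: float = 0.25
    gene_body_mch: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for v, what in [
            (self.mch_level, "mch_level"),
            (self.mcg_default, "mcg_default"),
            (self.mcg_cgi, "mcg_cgi"),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{what}={v} outside [0, 1]")
        for g, m in self.gene_body_mch.items():
            if m < 0:
                raise ValueError(f"gene_body_mch[{g!r}]={m} negative")


@dataclass
class MethylomeModel:
    """Cell-type levels plus a regional mCH landscape.

    Real CH methylation varies smoothly along the genome by several-fold;
    the landscape is modelled as a per-window lognormal multiplier (mean 1,
    log-sd ``regional_sigma``) shared by all cell types, on top of which the
    type-specific gene-body multipliers act.
    """

    cell_types: dict[str, CellTypeMethylome]
    regional_window: int = 2_000
    regional_sigma: float = 0.5

    def validate(self) -> None:
        if self.regional_window < 1 or self.regional_sigma < 0:
            raise ValueError("invalid regional landscape parameters")
        if not self.cell_types:
            raise ValueError("MethylomeModel needs at least one cell type")
        for ct in self.cell_types.values():
            ct.validate()
        if len(self.cell_types) >= 2:
            genes = set().union(*(ct.gene_body_mch for ct in self.cell_types.values()))
            markers = [g for g in genes if g in MARKER_GENES]
            if markers and not any(
                len({ct.gene_body_mch.get(g, 1.0) for ct in self.cell_types.values()}) >= 2
                for g in markers
            ):
                raise ValueError(
                    "marker genes must have distinct multipliers across cell types"
                )


def default_methylome_model() -> MethylomeModel:
    """Three cortical cell-type stand-ins with distinct global mCH and
    marker signatures.

    As in real neuronal methylomes, the types differ in gene-body mCH at many
    genes, not just the annotation markers; layer 2/3 excitatory cells are
    the type with low Cux1/Satb2 and high Rorb gene-body mCH.
    """
    return MethylomeModel(
        {
            "L23": CellTypeMethylome(
                mch_level=0.03,
                gene_body_mch={
                    "Cux1": 0.2, "Satb2": 0.2, "Rorb": 2.5,
                    "GeneA": 2.0, "GeneB": 0.3, "GeneC": 1.0, "GeneD": 1.5,
                    "GeneE": 0.5, "GeneF": 2.0, "GeneG": 0.4, "GeneH": 1.2,
                },
            ),
            "L45": CellTypeMethylome(
                mch_level=0.04,
                gene_body_mch={
                    "Cux1": 2.0, "Satb2": 0.5, "Rorb": 0.5,
                    "GeneA": 0.4, "GeneB": 1.8, "GeneC": 2.0, "GeneD": 0.3,
                    "GeneE": 1.6, "GeneF": 0.8, "GeneG": 1.5, "GeneH": 0.4,
                },
            ),
            "Inh": CellTypeMethylome(
                mch_level=0.06,
                gene_body_mch={
                    "Cux1": 1.2, "Satb2": 1.8, "Rorb": 0.8,
                    "GeneA": 1.0, "GeneB": 0.5, "GeneC": 0.4, "GeneD": 0.2,
                    "GeneE": 2.2, "GeneF": 0.3, "GeneG": 2.0, "GeneH": 1.8,
                },
            ),
        }
    )


class MethylomeTruth:
    """Per-cell binary methylation truth over the cytosine catalog."""

    def __init__(self, syn: SyntheticGenome, model: MethylomeModel,
                 cells: list[str], cell_types: dict[str, str],
                 meth: dict[str, np.ndarray], levels: dict[str, dict[str, np.ndarray]]):
        self.syn = syn
        self.model = model
        self.cells = cells
        self.cell_types = cell_types
        self.meth = meth          # contig -> bool (n_cells, n_sites)
        self.levels = levels      # cell type -> contig -> float (n_sites,)
        self._cell_row = {c: i for i, c in enumerate(cells)}

    def cell_row(self, cell: str) -> int:
        return self._cell_row[cell]

    def mean_level(self, cell: str, contig: str, site_mask: np.ndarray) -> float:
        """Truth methylated fraction over a subset of catalog sites."""
        row = self.meth[contig][self.cell_row(cell)]
        sel = row[site_mask]
        return float(sel.mean()) if sel.size else math.nan

    def global_truth_mch(self, cell: str) -> float:
        num = den = 0
        for contig in self.syn.genome.genomic_names():
            ch = ~self.syn.catalog[contig].cg
            num += int(self.meth[contig][self.cell_row(cell)][ch].sum())
            den += int(ch.sum())
        return num / den if den else math.nan

    def mean_cytosine_methylation(self) -> float:
        """Methylated fraction of cytosine sites pooled over cells/contigs
        (the m-bar entering post-bisulfite composition expectations)."""
        num = den = 0
        for contig in self.syn.genome.genomic_names():
            m = self.meth[contig]
            num += int(m.sum())
            den += m.size
        return num / den if den else math.nan


def simulate_methylome(
    syn: SyntheticGenome,
    model: MethylomeModel,
    n_cells_per_type: int | dict[str, int],
    seed: int = 0,
) -> MethylomeTruth:
    """Draw binary methylation states per cytosine per cell.

    Each site is an independent Bernoulli draw at the level appropriate to its
    context class (CG vs CH), region (CGI vs background for CG; gene-body
    multiplier for CH) and the cell's type. The spike-in contig is fully
    unmethylated.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    if isinstance(n_cells_per_type, int):
        n_cells_per_type = {t: n_cells_per_type for t in model.cell_types}

    cells, cell_types = [], {}
    for t in model.cell_types:
        for i in range(n_cells_per_type.get(t, 0)):
            cid = f"{t}_{i:03d}"
            cells.append(cid)
            cell_types[cid] = t

    # shared regional CH landscape: lognormal multiplier per window, mean 1
    genome = syn.genome
    regional: dict[str, np.ndarray] = {}
    for contig in genome.names:
        n_win = math.ceil(len(genome.contigs[contig]) / model.regional_window)
        s = model.regional_sigma
        regional[contig] = np.exp(rng.normal(-0.5 * s * s, s, size=n_win))

    levels: dict[str, dict[str, np.ndarray]] = {}
    for tname, ct in model.cell_types.items():
        levels[tname] = {}
        for contig in genome.names:
            cat = syn.catalog[contig]
            lev = np.zeros(cat.n)
            if contig == genome.lambda_contig:
                levels[tname][contig] = lev
                continue
            cgi = interval_mask(len(genome.arr(contig)), syn.cgi_intervals, contig)
            site_in_cgi = cgi[cat.pos]
            lev[cat.cg] = np.where(site_in_cgi[cat.cg], ct.mcg_cgi, ct.mcg_default)
            ch = ~cat.cg
            lev[ch] = ct.mch_level
            for row in syn.gene_models.itertuples(index=False):
                if row.contig != contig:
                    continue
                mult = ct.gene_body_mch.get(row.name)
                if mult is None:
                    continue
                in_gene = (cat.pos >= row.start) & (cat.pos < row.end) & ch
                lev[in_gene] = ct.mch_level * mult
            lev[ch] = lev[ch] * regional[contig][cat.pos[ch] // model.regional_window]
            levels[tname][contig] = np.clip(lev, 0.0, 1.0)

    meth: dict[str, np.ndarray] = {}
    for contig in genome.names:
        cat = syn.catalog[contig]
        m = np.zeros((len(cells), cat.n), dtype=bool)
        for i, cid in enumerate(cells):
            lev = levels[cell_types[cid]][contig]
            m[i] = rng.random(cat.n) < lev
        meth[contig] = m

    return MethylomeTruth(syn, model, cells, cell_types, meth, levels)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibraryParams:
    """Knobs of one cell's sequencing library."""

    conversion_rate: float = 0.995     # P(unmethylated C reads as T)
    read_length: int = 100
    insert_mean: float = 250.0
    insert_sd: float = 60.0
    barcode: str = DEFAULT_BARCODES[0]
    dimer_fraction: float = 0.06
    tail_mean: float = 8.0             # Adaptase tail, geometric mean (bp)
    tail_max: int = 50
    # per-base weights of tail bases in R2 read space; two-letter A/G by
    # default, uniform four-letter under dNTP carryover contamination
    tail_alphabet_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "G": 0.5}
    )
    duplicate_rate: float = 0.05
    seq_error_rate: float = 0.001
    lambda_spike_fraction: float = 0.01

    @classmethod
    def contaminated(cls, **kw) -> "LibraryParams":
        """Defaults under dNTP carryover: four-letter high-complexity tail."""
        kw.setdefault("tail_alphabet_weights", {b: 0.25 for b in BASES})
        return cls(**kw)

    def validate(self, barcode_set=None) -> None:
        for v, what in [
            (self.conversion_rate, "conversion_rate"),
            (self.dimer_fraction, "dimer_fraction"),
            (self.duplicate_rate, "duplicate_rate"),
            (self.seq_error_rate, "seq_error_rate"),
            (self.lambda_spike_fraction, "lambda_spike_fraction"),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{what}={v} outside [0, 1]")
        if not (self.tail_max >= self.tail_mean >= 0):
            raise ValueError("need tail_max >= tail_mean >= 0")
        w = sum(self.tail_alphabet_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"tail_alphabet_weights sum to {w}, expected 1")
        if any(b not in BASES for b in self.tail_alphabet_weights):
            raise ValueError("tail alphabet must be over A/C/G/T")
        if len(self.barcode) != BARCODE_LENGTH:
            raise ValueError(f"barcode must be {BARCODE_LENGTH} nt")
        if barcode_set is not None and self.barcode not in barcode_set:
            raise ValueError(f"barcode {self.barcode!r} not in configured set")
        if self.read_length <= BARCODE_LENGTH:
            raise ValueError("read_length must exceed the barcode length")


TRUTH_COLUMNS = [
    "read_id", "cell", "contig", "start", "end", "strand",
    "tail_len", "is_dimer", "is_duplicate", "is_lambda",
]


def _truncated_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    """Geometric on {0,1,...} with the given mean, truncated at cap
    (renormalised by resampling)."""
    if mean <= 0:
        return 0
    p = 1.0 / (1.0 + mean)
    while True:
        k = int(rng.geometric(p)) - 1
        if k <= cap:
            return k


def _apply_conversion(
    rng: np.random.Generator,
    watson_slice: np.ndarray,
    contig: str,
    start: int,
    strand: str,
    truth: MethylomeTruth | None,
    cell_row: int | None,
    conversion_rate: float,
) -> np.ndarray:
    """Bisulfite-convert a Watson-coordinate slice for the given original
    strand; returns the converted fragment 5'->3' on that strand."""
    arr = watson_slice.copy()
    n = len(arr)
    if strand == "+":
        cyt = np.nonzero(arr == C)[0]
        unconv_base, conv_base = C, T
    else:
        cyt = np.nonzero(arr == G)[0]
        unconv_base, conv_base = G, A  # Crick C->T appears as G->A on Watson
    if cyt.size:
        meth = np.zeros(cyt.size, dtype=bool)
        if truth is not None and cell_row is not None:
            cat = truth.syn.catalog[contig]
            mp = cat.plus_map if strand == "+" else cat.minus_map
            rows = mp[start + cyt]
            ok = rows >= 0
            meth[ok] = truth.meth[contig][cell_row][rows[ok]]
        convert = (~meth) & (rng.random(cyt.size) < conversion_rate)
        arr[cyt[convert]] = conv_base
    return arr if strand == "+" else revcomp_array(arr)


def _sequencing_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = seq_to_array(seq)
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in (A, C, G, T) if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return array_to_seq(arr)


def simulate_library(
    syn: SyntheticGenome,
    truth: MethylomeTruth | None,
    cell_id: str,
    params: LibraryParams,
    n_pairs: int,
    seed: int = 0,
    barcode_set=None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate one cell's paired-end library plus its per-read truth table."""
    params.validate(barcode_set=barcode_set)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    genome = syn.genome
    cell_row = truth.cell_row(cell_id) if truth is not None else None

    gnames = genome.genomic_names()
    glens = np.array([len(genome.contigs[n]) for n in gnames], dtype=float)
    gprobs = glens / glens.sum() if gnames else None
    lam = genome.lambda_contig

    tail_letters = sorted(params.tail_alphabet_weights)
    tail_w = np.array([params.tail_alphabet_weights[b] for b in tail_letters])

    rl = params.read_length
    molecules: list[tuple[str, str, dict]] = []  # (r1_pre_error, r2_pre_error, truth row)
    pairs: list[ReadPair] = []
    rows: list[dict] = []

    for i in range(n_pairs):
        read_id = f"{cell_id}:{i:06d}"
        tail_len = _truncated_geometric(rng, params.tail_mean, params.tail_max)
        tail = "".join(
            tail_letters[j] for j in rng.choice(len(tail_letters), size=tail_len, p=tail_w)
        )

        if molecules and rng.random() < params.duplicate_rate:
            r1_pre, r2_pre, src = molecules[rng.integers(len(molecules))]
            row = dict(src, read_id=read_id, is_duplicate=True)
        elif rng.random() < params.dimer_fraction:
            r1_pre = (params.barcode + ADAPTER_R1 * 4)[:rl]
            r2_body = ADAPTER_R2 * 4
            r2_pre = (tail + r2_body)[:rl]
            row = dict(
                read_id=read_id, cell=cell_id, contig="*", start=-1, end=-1,
                strand=".", tail_len=tail_len, is_dimer=True,
                is_duplicate=False, is_lambda=False,
            )
            molecules.append((r1_pre, r2_pre, row))
        else:
            is_lambda = lam is not None and rng.random() < params.lambda_spike_fraction
            if is_lambda:
                contig = lam
            else:
                contig = gnames[rng.choice(len(gnames), p=gprobs)]
            clen = len(genome.contigs[contig])
            while True:
                insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
                if 1 <= insert <= clen:
                    break
            start = int(rng.integers(0, clen - insert + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            frag = _apply_conversion(
                rng, genome.arr(contig)[start : start + insert], contig, start,
                strand, truth if not is_lambda else truth, cell_row,
                params.conversion_rate,
            )
            frag_s = array_to_seq(frag)
            r1_pre = (params.barcode + array_to_seq(revcomp_array(frag)) + ADAPTER_R1 * 4)[:rl]
            r2_pre = (tail + frag_s + ADAPTER_R2 * 4)[:rl]
            row = dict(
                read_id=read_id, cell=cell_id, contig=contig, start=start,
                end=start + insert, strand=strand, tail_len=tail_len,
                is_dimer=False, is_duplicate=False, is_lambda=bool(is_lambda),
            )
            molecules.append((r1_pre, r2_pre, row))

        pairs.append(
            ReadPair(
                read_id,
                _sequencing_errors(rng, r1_pre, params.seq_error_rate),
                _sequencing_errors(rng, r2_pre, params.seq_error_rate),
            )
        )
        rows.append(row)

    truth_df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return pairs, truth_df


def simulate_run(
    syn: SyntheticGenome,
    truth: MethylomeTruth,
    params: LibraryParams,
    n_pairs_per_cell: int,
    seed: int = 0,
    barcodes: tuple[str, ...] = DEFAULT_BARCODES,
) -> tuple[dict[str, list[ReadPair]], pd.DataFrame, dict[str, str]]:
    """Simulate every cell in the truth set as a multiplexed run.

    Cells are assigned in-line barcodes cyclically; each group of
    ``len(barcodes)`` cells forms one "plate" (one dual-index pair, hence one
    multiplexed FASTQ pair). Returns plate -> shuffled read pairs, the pooled
    truth table, and the cell -> barcode map.
    """
    rng = np.random.default_rng(seed)
    plates: dict[str, list[ReadPair]] = {}
    cell_barcode: dict[str, str] = {}
    truth_tables = []
    for j, cell in enumerate(truth.cells):
        bc = barcodes[j % len(barcodes)]
        plate = f"P{j // len(barcodes) + 1:03d}"
        cell_barcode[cell] = bc
        p = LibraryParams(**{**params.__dict__, "barcode": bc})
        cell_seed = int(rng.integers(0, 2**31 - 1))
        reads, tdf = simulate_library(
            syn, truth, cell, p, n_pairs_per_cell, seed=cell_seed,
            barcode_set=barcodes,
        )
        plates.setdefault(plate, []).extend(reads)
        truth_tables.append(tdf)
    for plate in plates:
        order = rng.permutation(len(plates[plate]))
        plates[plate] = [plates[plate][k] for k in order]
    return plates, pd.concat(truth_tables, ignore_index=True), cell_barcode
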