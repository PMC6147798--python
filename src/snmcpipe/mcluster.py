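"""Methylome clustering: genome-bin mCH matrices, coverage filtering,
global-mCH normalisation, PCA + hierarchical clustering, marker-gene
annotation and cross-dataset correlation.

The substrate is the cell x bin matrix of CH methylation ratios over
non-overlapping genome-anchored tiles (default 100 kb; bin i of a contig
covers [i*size, (i+1)*size)). Bins are kept only when more than a fraction of
cells have more than a minimum number of CH basecalls in them (strict
inequalities at both levels). Ratios are divided by each cell's global mCH —
making the embedding invariant to global methylation scale — imputed at the
across-cell bin mean where a kept bin is uncovered, column-centred and
reduced by PCA; agglomerative (Ward) clustering on the leading components
yields clusters, annotated by gene-body mCH at marker genes (layer 2/3
excitatory neurons: low at Cux1 and Satb2, high at Rorb).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .genome import Genome
from .mcall import context_class

DEFAULT_BIN_SIZE = 100_000
DEFAULT_MIN_BASECALLS = 100
DEFAULT_MIN_CELL_FRACTION = 0.975
DEFAULT_N_PCS = 150


@dataclass
class BinMatrix:
    """Per-cell methylated / total CH basecalls in genome bins."""

    cells: list[str]
    bins: pd.DataFrame          # contig, start, end
    mc: np.ndarray              # (n_cells, n_bins) int
    cov: np.ndarray

    def __post_init__(self):
        if self.mc.shape != self.cov.shape or self.mc.shape != (
            len(self.cells), len(self.bins),
        ):
            raise ValueError("inconsistent BinMatrix shapes")
        if (self.mc > self.cov).any():
            raise ValueError("mc exceeds cov")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def ratio(self) -> np.ndarray:
        """mc/cov with NaN where a bin is uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.mc / self.cov
        return np.where(self.cov > 0, r, np.nan)


def make_bins(genome: Genome, bin_size: int = DEFAULT_BIN_SIZE,
              exclude_contigs: tuple[str, ...] = ()) -> pd.DataFrame:
    rows = []
    for name, length in genome.lengths.items():
        if name in exclude_contigs:
            continue
        for start in range(0, length, bin_size):
            rows.append((name, start, min(start + bin_size, length)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def bin_mch(
    allc_by_cell: dict[str, pd.DataFrame],
    genome: Genome,
    bin_size: int = DEFAULT_BIN_SIZE,
    exclude_spike_in: bool = True,
) -> BinMatrix:
    """Aggregate CH-class basecalls of each cell into genome bins."""
    exclude = (genome.lambda_contig,) if (exclude_spike_in and genome.lambda_contig) else ()
    bins = make_bins(genome, bin_size, exclude_contigs=exclude)
    bin_offset = {}
    off = 0
    for name, length in genome.lengths.items():
        if name in exclude:
            continue
        bin_offset[name] = off
        off += math.ceil(length / bin_size)

    cells = list(allc_by_cell)
    mc = np.zeros((len(cells), len(bins)), dtype=np.int64)
    cov = np.zeros_like(mc)
    lengths = genome.lengths
    for i, cell in enumerate(cells):
        allc = allc_by_cell[cell]
        if len(allc) == 0:
            continue
        ch = allc[context_class(allc["context"]) == "CH"]
        ch = ch[ch["contig"].isin(bin_offset)]
        if len(ch) == 0:
            continue
        pos0 = ch["pos"].to_numpy() - 1
        contigs = ch["contig"].to_numpy()
        if ((pos0 < 0) | (pos0 >= np.array([lengths[c] for c in contigs]))).any():
            raise ValueError(f"cell {cell}: allc positions outside contigs")
        idx = np.array([bin_offset[c] for c in contigs]) + pos0 // bin_size
        np.add.at(mc[i], idx, ch["mc"].to_numpy())
        np.add.at(cov[i], idx, ch["cov"].to_numpy())
    return BinMatrix(cells, bins, mc, cov)


def filter_bins(
    bm: BinMatrix,
    min_basecalls: int = DEFAULT_MIN_BASECALLS,
    min_cell_fraction: float = DEFAULT_MIN_CELL_FRACTION,
) -> BinMatrix:
    """Keep bins with > min_basecalls in more than min_cell_fraction of
    cells (both inequalities strict). Idempotent."""
    n_cells = len(bm.cells)
    n_ok = (bm.cov > min_basecalls).sum(axis=0)
    keep = n_ok > min_cell_fraction * n_cells
    if not keep.any():
        raise ValueError(
            "no bins survive the coverage filter; lower min_basecalls / "
            "min_cell_fraction or increase bin size / sequencing depth"
        )
    return BinMatrix(
        bm.cells, bm.bins.loc[keep].reset_index(drop=True),
        bm.mc[:, keep], bm.cov[:, keep],
    )


@dataclass
class Embedding:
    cells: list[str]
    components: np.ndarray          # (n_cells, n_pcs)
    explained_variance_ratio: np.ndarray
    excluded_cells: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.components, index=self.cells,
            columns=[f"PC{i + 1}" for i in range(self.components.shape[1])],
        )
        df.index.name = "cell"
        return df


def normalize_ratios(
    bm: BinMatrix, global_mch: dict[str, float]
) -> tuple[list[str], np.ndarray, list[str]]:
    """Bin ratios imputed at the across-cell bin mean and divided by each
    cell's global mCH; cells with non-positive/missing global mCH are
    excluded. Returns (kept cells, matrix, excluded cells)."""
    keep_cells, excluded = [], []
    for c in bm.cells:
        g = global_mch.get(c, math.nan)
        if g is None or not np.isfinite(g) or g <= 0:
            excluded.append(c)
        else:
            keep_cells.append(c)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} cell(s) with non-positive global mCH: "
            f"{excluded}"
        )
    rows = [bm.cells.index(c) for c in keep_cells]
    ratio = bm.ratio()[rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_mean = np.nanmean(ratio, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    ratio = np.where(np.isnan(ratio), col_mean[None, :], ratio)
    g = np.array([global_mch[c] for c in keep_cells])
    return keep_cells, ratio / g[:, None], excluded


def normalize_and_embed(
    bm: BinMatrix,
    global_mch: dict[str, float],
    n_pcs: int = DEFAULT_N_PCS,
) -> Embedding:
    """Divide bin ratios by each cell's global mCH, impute uncovered entries
    with the across-cell bin mean, centre columns, and return the top
    min(n_pcs, rank) principal components."""
    keep_cells, norm, excluded = normalize_ratios(bm, global_mch)
    if len(keep_cells) < 2:
        raise ValueError("need at least 2 cells with positive global mCH")
    n_comp = min(n_pcs, len(keep_cells) - 1, norm.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    comps = pca.fit_transform(norm)  # centres columns internally
    return Embedding(keep_cells, comps, pca.explained_variance_ratio_, excluded)


@dataclass
class ClusterAssignment:
    cells: list[str]
    labels: np.ndarray                       # 1..k cluster ids
    k: int
    linkage: np.ndarray = field(repr=False, default=None)
    annotations: dict[int, str] = field(default_factory=dict)
    ambiguous: bool = False
    marker_evidence: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cells,
                "cluster": self.labels,
                "annotation": [self.annotations.get(int(l), "") for l in self.labels],
            }
        )


def cluster_cells(embedding: Embedding, k: int | None = None) -> ClusterAssignment:
    """Ward hierarchical clustering on the principal components.

    With k unset, the tree is cut at the largest merge-height gap; all-equal
    rows (every merge at height ~0) collapse to a single cluster.
    """
    X = embedding.components
    n = X.shape[0]
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k={k} outside [1, {n}]")
    Z = hierarchy.linkage(X, method="ward")
    if k is None:
        heights = Z[:, 2]
        if heights[-1] <= 1e-12:
            k = 1
        elif n == 2:
            k = 2
        else:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            k = n - (i + 1)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(list(embedding.cells), labels, int(labels.max()), Z)


# ---------------------------------------------------------------------------
# Marker annotation
# ---------------------------------------------------------------------------

@dataclass
class MarkerRule:
    label: str
    low: tuple[str, ...]
    high: tuple[str, ...]


L23_RULE = MarkerRule("L2/3 excitatory", low=("Cux1", "Satb2"), high=("Rorb",))


def gene_body_mch(
    allc_by_cell: dict[str, pd.DataFrame],
    cells: list[str],
    gene_intervals: pd.DataFrame,
    genes: list[str],
) -> pd.Series:
    """Pooled gene-body mCH over a set of cells, one value per gene."""
    out = {}
    for gene in genes:
        sub = gene_intervals[gene_intervals["name"] == gene]
        if len(sub) == 0:
            raise ValueError(f"marker gene {gene!r} absent from the annotation")
        mc = cov = 0
        for row in sub.itertuples(index=False):
            for cell in cells:
                allc = allc_by_cell[cell]
                if len(allc) == 0:
                    continue
                m = (
                    (allc["contig"] == row.contig)
                    & (allc["pos"] - 1 >= row.start)
                    & (allc["pos"] - 1 < row.end)
                    & (context_class(allc["context"]) == "CH")
                )
                mc += int(allc.loc[m, "mc"].sum())
                cov += int(allc.loc[m, "cov"].sum())
        out[gene] = mc / cov if cov else math.nan
    return pd.Series(out, name="mch")


def annotate_clusters(
    assignment: ClusterAssignment,
    allc_by_cell: dict[str, pd.DataFrame],
    gene_intervals: pd.DataFrame,
    rules: list[MarkerRule] = (L23_RULE,),
) -> ClusterAssignment:
    """Label clusters whose marker gene-body mCH satisfies a rule: every
    "low" gene strictly below, every "high" gene strictly above, the
    across-cluster median for that gene. Several satisfying clusters are all
    labelled and flagged ambiguous; none leaves the rule unassigned."""
    genes = sorted({g for r in rules for g in (*r.low, *r.high)})
    clusters = sorted(set(int(l) for l in assignment.labels))
    evidence = pd.DataFrame(index=clusters, columns=genes, dtype=float)
    for cl in clusters:
        cells = [c for c, l in zip(assignment.cells, assignment.labels) if l == cl]
        evidence.loc[cl] = gene_body_mch(allc_by_cell, cells, gene_intervals, genes)
    evidence.index.name = "cluster"

    annotations: dict[int, str] = {}
    ambiguous = False
    medians = evidence.median(axis=0)
    for rule in rules:
        hits = [
            cl
            for cl in clusters
            if all(evidence.loc[cl, g] < medians[g] for g in rule.low)
            and all(evidence.loc[cl, g] > medians[g] for g in rule.high)
        ]
        if len(hits) > 1:
            ambiguous = True
        for cl in hits:
            annotations[cl] = rule.label
    return ClusterAssignment(
        assignment.cells, assignment.labels, assignment.k, assignment.linkage,
        annotations, ambiguous, evidence,
    )


# ---------------------------------------------------------------------------
# Cross-dataset correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_intervals: int


def _pooled_interval_ratios(
    allc_tables: list[pd.DataFrame], intervals: pd.DataFrame, context: str
) -> tuple[np.ndarray, np.ndarray]:
    mc = np.zeros(len(intervals))
    cov = np.zeros(len(intervals))
    for allc in allc_tables:
        if len(allc) == 0:
            continue
        cls = context_class(allc["context"])
        sub = allc[cls == context]
        for i, row in enumerate(intervals.itertuples(index=False)):
            m = (
                (sub["contig"] == row.contig)
                & (sub["pos"] - 1 >= row.start)
                & (sub["pos"] - 1 < row.end)
            )
            mc[i] += sub.loc[m, "mc"].sum()
            cov[i] += sub.loc[m, "cov"].sum()
    return mc, cov


def aggregate_and_correlate(
    allc_a: list[pd.DataFrame],
    allc_b: list[pd.DataFrame],
    intervals: pd.DataFrame,
    context: str = "CH",
) -> CorrelationResult:
    """Pearson correlation of pooled interval methylation ratios between two
    datasets on the same genome, over intervals covered in both."""
    mc_a, cov_a = _pooled_interval_ratios(allc_a, intervals, context)
    mc_b, cov_b = _pooled_interval_ratios(allc_b, intervals, context)
    shared = (cov_a > 0) & (cov_b > 0)
    n = int(shared.sum())
    if n < 3:
        raise ValueError(f"only {n} intervals covered in both datasets (need >= 3)")
    ra = mc_a[shared] / cov_a[shared]
    rb = mc_b[shared] / cov_b[shared]
    r, p = pearsonr(ra, rb)
    return CorrelationResult(float(r), float(p), n)
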