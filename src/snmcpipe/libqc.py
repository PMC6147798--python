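"""Per-cell QC: library-complexity extrapolation, coverage uniformity,
CGI enrichment, QC table assembly and group comparisons.

Library complexity uses the Good-Toulmin estimator on the duplication
histogram n_j (number of distinct loci observed exactly j times): the
expected number of *new* loci after scaling sampling by t is

    Delta(t) = sum_j (-1)^(j+1) (t-1)^j n_j.

For t - 1 > 1 the raw alternating series is numerically explosive and is
summed via Euler transformation (repeated averaging of partial sums) — the
classical tame replacement for rational-function acceleration. Estimates are
clamped to [observed, genome capacity] and complexity curves are forced
monotone, matching the estimator's theoretical behaviour where it is valid.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bsalign import AlignmentHit
from .genome import Genome, interval_mask

REFERENCE_DEPTH_PAIRS = 50_000_000
MAX_EXTRAPOLATION = 5e9
EXTRAPOLATION_STEP = 1e7


@dataclass
class DuplicationHistogram:
    """n_j = number of loci seen exactly j times; sum(j * n_j) = total reads."""

    counts: dict[int, int]

    @property
    def total_reads(self) -> int:
        return sum(j * n for j, n in self.counts.items())

    @property
    def distinct(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        if any(j < 1 or n < 0 for j, n in self.counts.items()):
            raise ValueError("histogram keys must be >= 1 and counts >= 0")


def duplication_histogram(hits: list[AlignmentHit]) -> DuplicationHistogram:
    """Histogram over (contig, start, frame) loci of MAPQ-passing reads
    (pre clonal collapse) of a single cell."""
    mult = Counter((h.contig, h.start, h.frame) for h in hits)
    return DuplicationHistogram(dict(Counter(mult.values())))


def _euler_sum(terms: np.ndarray) -> float:
    """Sum of sum_i terms[i] for an alternating (signed) sequence via the
    Euler transformation: repeatedly average adjacent partial sums."""
    p = np.cumsum(terms)
    while len(p) > 1:
        p = 0.5 * (p[:-1] + p[1:])
    return float(p[0])


def good_toulmin_delta(
    hist: DuplicationHistogram, t: float, method: str = "auto"
) -> float:
    """Expected new distinct loci when sampling is scaled from 1 to t."""
    if t < 1:
        raise ValueError("t must be >= 1")
    s = t - 1.0
    if s == 0 or not hist.counts:
        return 0.0
    jmax = max(hist.counts)
    n = np.array([hist.counts.get(j, 0) for j in range(1, jmax + 1)], dtype=float)
    signs = np.array([(-1.0) ** (j + 1) for j in range(1, jmax + 1)])
    terms = signs * n * s ** np.arange(1, jmax + 1)
    if method == "direct":
        if s > 1:
            raise ValueError(
                "direct Good-Toulmin series diverges for t - 1 > 1; "
                "use the Euler-transformed mode"
            )
        return float(terms.sum())
    if method not in ("auto", "euler"):
        raise ValueError(f"unknown method {method!r}")
    if s <= 1 and method == "auto":
        return float(terms.sum())
    return _euler_sum(terms)


@dataclass
class ComplexityEstimate:
    distinct: float
    target_reads: float
    total_reads: int
    fraction_of_genome: float | None = None


def extrapolate_complexity(
    hist: DuplicationHistogram,
    target_reads: float,
    genome_size: int | None = None,
    read_span: float | None = None,
    method: str = "auto",
) -> ComplexityEstimate:
    """Expected distinct loci at a deeper sequencing depth.

    ``read_span`` (mean retained read length) converts distinct loci into an
    approximate fraction of the genome covered, the Table-1-style complexity
    statistic; the locus count itself is capped at the genome size.
    """
    hist.validate()
    total = hist.total_reads
    if total == 0:
        raise ValueError("empty duplication histogram")
    if target_reads < total:
        raise ValueError("target_reads must be >= observed reads")
    t = target_reads / total
    delta = good_toulmin_delta(hist, t, method=method)
    distinct = hist.distinct + max(0.0, delta)
    if genome_size is not None:
        distinct = min(distinct, float(genome_size))
    frac = None
    if genome_size is not None and read_span is not None:
        frac = min(1.0, distinct * read_span / genome_size)
    return ComplexityEstimate(distinct, target_reads, total, frac)


def complexity_curve(
    hist: DuplicationHistogram,
    max_extrapolation: float = MAX_EXTRAPOLATION,
    step: float = EXTRAPOLATION_STEP,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Monotone distinct-locus curve on a depth grid (gc_extrap-style
    defaults: bound 5e9 reads in 1e7 steps)."""
    hist.validate()
    total = hist.total_reads
    targets = np.arange(total, max_extrapolation + step, step)
    if targets[0] > total:
        targets = np.concatenate([[total], targets])
    vals = []
    for tr in targets:
        d = good_toulmin_delta(hist, tr / total)
        vals.append(hist.distinct + max(0.0, d))
    vals = np.maximum.accumulate(np.asarray(vals))
    if genome_size is not None:
        vals = np.minimum(vals, genome_size)
    return pd.DataFrame({"target_reads": targets, "distinct": vals})


# ---------------------------------------------------------------------------
# Coverage uniformity
# ---------------------------------------------------------------------------

def coverage_track(hits: list[AlignmentHit], genome: Genome) -> dict[str, np.ndarray]:
    """Per-position read depth from (possibly pooled) alignment hits."""
    depth = {n: np.zeros(l, dtype=np.int64) for n, l in genome.lengths.items()}
    for h in hits:
        d = depth[h.contig]
        d[h.start : h.start + h.length] += 1
    return depth


def cg_sites(genome: Genome, contig: str) -> np.ndarray:
    """Start positions of CG dinucleotides on a contig (Watson)."""
    from ._seqops import C, G

    arr = genome.arr(contig)
    return np.nonzero((arr[:-1] == C) & (arr[1:] == G))[0]


@dataclass
class UniformityReport:
    cg_depth_mean: float
    cg_depth_sd: float
    bin_cv: dict[int, float]
    cgi_enrichment: float
    flagged: bool = False


def uniformity(
    depth: dict[str, np.ndarray],
    genome: Genome,
    cgi_intervals: pd.DataFrame,
    bin_sizes: tuple[int, ...] = (1_000, 10_000),
) -> UniformityReport:
    """Per-CG-site depth statistics, per-bin coverage CV and CGI enrichment.

    CG-site statistics use sites with depth >= 1 (the covered set). CGI
    enrichment is mean depth inside CGI intervals over the genome-wide mean.
    The spike-in contig is excluded throughout.
    """
    names = genome.genomic_names()
    site_depths, all_depth, cgi_depth = [], [], []
    bin_means: dict[int, list[float]] = {b: [] for b in bin_sizes}
    for name in names:
        d = depth[name]
        sites = cg_sites(genome, name)
        if sites.size:
            site_depths.append(d[sites])
        all_depth.append(d)
        mask = interval_mask(len(d), cgi_intervals, name)
        if mask.any():
            cgi_depth.append(d[mask])
        for b in bin_sizes:
            edges = np.arange(0, len(d) + b, b)
            for lo, hi in zip(edges[:-1], edges[1:]):
                hi = min(hi, len(d))
                if hi > lo:
                    bin_means[b].append(float(d[lo:hi].mean()))

    genome_mean = float(np.concatenate(all_depth).mean()) if all_depth else 0.0
    if genome_mean == 0.0:
        return UniformityReport(math.nan, math.nan, {b: math.nan for b in bin_sizes},
                                math.nan, flagged=True)

    sd_all = np.concatenate(site_depths) if site_depths else np.array([])
    covered = sd_all[sd_all > 0]
    cg_mean = float(covered.mean()) if covered.size else math.nan
    cg_sd = float(covered.std(ddof=0)) if covered.size else math.nan

    cv = {}
    for b in bin_sizes:
        m = np.asarray(bin_means[b])
        cv[b] = float(m.std(ddof=0) / m.mean()) if m.size and m.mean() > 0 else math.nan

    enrich = (
        float(np.concatenate(cgi_depth).mean() / genome_mean) if cgi_depth else math.nan
    )
    return UniformityReport(cg_mean, cg_sd, cv, enrich)


# ---------------------------------------------------------------------------
# QC table assembly and group comparison
# ---------------------------------------------------------------------------

QC_COLUMNS = [
    "cell", "input_pairs", "assigned_pairs", "kept_pairs", "dimer_or_short",
    "dimer_fraction", "r1_mapping_rate", "r2_mapping_rate",
    "combined_mapping_rate", "retained_nonclonal", "conversion_rate",
    "passes_conversion", "mcg", "mch", "distinct_loci",
    "complexity_fraction", "missing_fields",
]


def assemble_qc(
    cells: list[str],
    demux_counts: dict[str, int] | None = None,
    input_pairs: dict[str, int] | None = None,
    trim_reports: dict[str, pd.DataFrame] | None = None,
    map_counts: dict[str, dict[str, int]] | None = None,
    retained: dict[str, int] | None = None,
    conversion: dict[str, "object"] | None = None,
    levels: dict[str, "object"] | None = None,
    complexity: dict[str, ComplexityEstimate] | None = None,
) -> pd.DataFrame:
    """One QC row per cell; missing stages leave flagged NaN fields.

    Enforces the count conservation assigned = kept + dimer_or_short.
    """
    from .bsalign import mapping_rate as _mrate

    rows = []
    for cell in cells:
        row: dict = {c: math.nan for c in QC_COLUMNS}
        row["cell"] = cell
        missing = []
        row["input_pairs"] = (input_pairs or {}).get(cell, math.nan)
        assigned = (demux_counts or {}).get(cell)
        if assigned is None:
            missing.append("demux")
        else:
            row["assigned_pairs"] = assigned
        tr = (trim_reports or {}).get(cell)
        if tr is None:
            missing.append("trim")
        else:
            kept = int((tr["klass"] == "keep").sum())
            dimer = int((tr["klass"] == "dimer_or_short").sum())
            row["kept_pairs"], row["dimer_or_short"] = kept, dimer
            if assigned is not None:
                if kept + dimer != assigned:
                    raise ValueError(
                        f"cell {cell}: kept ({kept}) + dimer_or_short ({dimer}) "
                        f"!= assigned ({assigned})"
                    )
                row["dimer_fraction"] = dimer / assigned if assigned else math.nan
        mc = (map_counts or {}).get(cell)
        if mc is None:
            missing.append("align")
        else:
            r = _mrate(mc)
            row["r1_mapping_rate"] = r["r1"]
            row["r2_mapping_rate"] = r["r2"]
            row["combined_mapping_rate"] = r["combined"]
        if retained is not None and cell in retained:
            row["retained_nonclonal"] = retained[cell]
        conv = (conversion or {}).get(cell)
        if conv is None:
            missing.append("conversion")
        elif conv.flagged:
            missing.append("conversion")
            row["passes_conversion"] = False
        else:
            row["conversion_rate"] = conv.rate
            row["passes_conversion"] = conv.passes_threshold
        lev = (levels or {}).get(cell)
        if lev is None:
            missing.append("levels")
        else:
            row["mcg"], row["mch"] = lev.mcg, lev.mch
        cx = (complexity or {}).get(cell)
        if cx is None:
            missing.append("complexity")
        else:
            row["distinct_loci"] = cx.distinct
            row["complexity_fraction"] = cx.fraction_of_genome
        row["missing_fields"] = ",".join(missing)
        rows.append(row)
    return pd.DataFrame(rows, columns=QC_COLUMNS)


@dataclass
class GroupComparison:
    difference: float
    t_statistic: float
    p_value: float


def compare_groups(a, b) -> GroupComparison:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance
        if diff == 0:
            return GroupComparison(0.0, 0.0, 1.0)
        return GroupComparison(diff, math.inf if diff > 0 else -math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(diff, float(t), float(p))
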