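"""Per-cytosine methylation calling into allc-style tables.

A retained CT-frame hit reports Watson cytosines: an aligned read C is a
methylated basecall, an aligned read T an unmethylated one; any other read
base at a cytosine is ignored. GA-frame hits are the mirror image on Crick
cytosines (read G methylated, read A unmethylated, reported on the ``-``
strand at the same Watson coordinate). Positions are 1-based in the output,
contexts are the trinucleotide on the cytosine's own strand, collapsed to the
CG/CH classes downstream. Overlapping mates are resolved by keeping R1's
basecalls.

The dialect is 7 columns: contig, pos, strand, context, mc, cov, methylated —
the last a convenience flag from a one-sided binomial test of mc/cov against
the conversion-failure rate (1 - conversion_rate) at p < 0.01.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seqops import A, C, G, T, seq_to_array
from .bsalign import AlignmentHit
from .genome import CytosineCatalog, Genome

ALLC_COLUMNS = ["contig", "pos", "strand", "context", "mc", "cov", "methylated"]


def context_class(context: pd.Series) -> pd.Series:
    """Collapse trinucleotide contexts to the CG / CH classes."""
    return np.where(context.str[1] == "G", "CG", "CH")


def call_methylation(
    hits: list[AlignmentHit],
    genome: Genome,
    catalog: CytosineCatalog,
    conversion_rate: float = 0.995,
    flag_alpha: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Aggregate filtered hits into one allc table per cell."""
    per_cell: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def _arrays(cell: str, contig: str):
        cells = per_cell.setdefault(cell, {})
        if contig not in cells:
            n = catalog[contig].n
            cells[contig] = (np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))
        return cells[contig]

    # R1 intervals per pair for mate-overlap resolution (R1 wins)
    r1_span: dict[tuple[str, str], tuple[str, str, int, int]] = {}
    for h in hits:
        if h.mate == 1:
            r1_span[(h.cell, h.read_id)] = (h.contig, h.frame, h.start, h.start + h.length)

    for h in hits:
        cat = catalog[h.contig]
        mc_arr, cov_arr = _arrays(h.cell, h.contig)
        read = seq_to_array(h.seq_fwd)
        if h.frame == "CT":
            rows = cat.plus_map[h.start : h.start + h.length]
            meth_b, unmeth_b = C, T
        else:
            rows = cat.minus_map[h.start : h.start + h.length]
            meth_b, unmeth_b = G, A
        valid = rows >= 0
        if h.mate == 2:
            span = r1_span.get((h.cell, h.read_id))
            if span is not None and span[0] == h.contig and span[1] == h.frame:
                pos = np.arange(h.start, h.start + h.length)
                valid &= ~((pos >= span[2]) & (pos < span[3]))
        is_mc = valid & (read == meth_b)
        is_cov = is_mc | (valid & (read == unmeth_b))
        np.add.at(mc_arr, rows[is_mc], 1)
        np.add.at(cov_arr, rows[is_cov], 1)

    p0 = 1.0 - conversion_rate
    out: dict[str, pd.DataFrame] = {}
    for cell, contigs in per_cell.items():
        frames = []
        for contig, (mc_arr, cov_arr) in contigs.items():
            cat = catalog[contig]
            sel = cov_arr > 0
            if not sel.any():
                continue
            mc, cov = mc_arr[sel], cov_arr[sel]
            flag = stats.binom.sf(mc - 1, cov, p0) < flag_alpha
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": cat.pos[sel] + 1,
                        "strand": np.where(cat.watson[sel], "+", "-"),
                        "context": cat.context[sel],
                        "mc": mc,
                        "cov": cov,
                        "methylated": flag,
                    }
                )
            )
        out[cell] = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=ALLC_COLUMNS)
        )
    return out


@dataclass
class ConversionEstimate:
    nonconverted: int
    total: int

    @property
    def rate(self) -> float:
        return 1.0 - self.nonconverted / self.total if self.total else math.nan

    @property
    def passes_threshold(self) -> bool:
        return self.total > 0 and self.rate >= 0.99

    @property
    def flagged(self) -> bool:
        """True when no spike-in basecalls were observed (rate undefined)."""
        return self.total == 0


def estimate_conversion(allc: pd.DataFrame, lambda_contig: str) -> ConversionEstimate:
    """Bisulfite conversion rate from the unmethylated spike-in contig:
    1 - (methylated basecalls / total cytosine basecalls)."""
    sub = allc[allc["contig"] == lambda_contig]
    return ConversionEstimate(int(sub["mc"].sum()), int(sub["cov"].sum()))


@dataclass
class GlobalLevels:
    mcg: float
    mch: float
    mcg_cov: int
    mch_cov: int

    @property
    def flagged(self) -> bool:
        return self.mcg_cov == 0 or self.mch_cov == 0


def global_levels(
    allc: pd.DataFrame, exclude_contigs: tuple[str, ...] = ()
) -> GlobalLevels:
    """Global mCG and mCH of a cell: pooled mc/cov per context class."""
    if len(allc) == 0:
        return GlobalLevels(math.nan, math.nan, 0, 0)
    sub = allc[~allc["contig"].isin(exclude_contigs)]
    cls = context_class(sub["context"])
    res = {}
    for name in ("CG", "CH"):
        s = sub[cls == name]
        cov = int(s["cov"].sum())
        res[name] = (float(s["mc"].sum() / cov) if cov else math.nan, cov)
    return GlobalLevels(res["CG"][0], res["CH"][0], res["CG"][1], res["CH"][1])


def correct_for_conversion_failure(apparent: float, conversion_rate: float) -> float:
    """Optional utility removing the conversion-failure inflation from an
    apparent methylation level: m = (apparent - (1-c)) / c, floored at 0.
    Reported pipeline levels are raw (uncorrected)."""
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0, 1]")
    return max(0.0, (apparent - (1.0 - conversion_rate)) / conversion_rate)


def write_allc(allc: pd.DataFrame, path) -> None:
    allc.to_csv(path, sep="\t", index=False)


def read_allc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
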