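"""Demultiplexing, adapter/tail trimming and base-composition diagnostics.

The R2 5' tail detector is a first-exit rule: the detected tail is the longest
read prefix consisting solely of bases from the configured low-complexity tail
alphabet, capped at ``tail_max``. Past the true tail boundary the detector
keeps extending only while genomic bases happen to fall in the alphabet, so
its overshoot is geometric with mean q/(1-q), where q is the in-alphabet rate
of post-tail sequence. ``tail_length_summary`` measures q from read positions
beyond ``tail_max`` and reports a bias-corrected mean tail length alongside
the raw mean; the corrected value is the detector's estimate of the tail
model mean.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqops import hamming
from .genome import Genome, ReadPair
from .synthio import (
    ADAPTER_R1,
    ADAPTER_R2,
    BARCODE_LENGTH,
    DEFAULT_BARCODES,
    MethylomeTruth,
)

DEFAULT_INDEX_PAIRS = tuple(f"P{i:03d}" for i in range(1, 769))


@dataclass
class BarcodeSet:
    """In-line barcodes plus dual-index pair labels.

    The pairwise Hamming distance must exceed ``2 * max_mismatch`` so that
    every read prefix is within ``max_mismatch`` of at most one barcode.
    """

    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    max_mismatch: int = 1
    index_pairs: tuple[str, ...] = DEFAULT_INDEX_PAIRS

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        lens = {len(b) for b in self.barcodes}
        if lens != {BARCODE_LENGTH}:
            raise ValueError(f"barcodes must all be {BARCODE_LENGTH} nt")
        for a, b in itertools.combinations(self.barcodes, 2):
            d = hamming(a, b)
            if d <= 2 * self.max_mismatch:
                raise ValueError(
                    f"barcodes {a}/{b} at Hamming distance {d} <= "
                    f"2*max_mismatch={2 * self.max_mismatch}: assignment ambiguous"
                )

    @property
    def n_labels(self) -> int:
        """Distinct multiplexed cell labels (barcodes x dual-index pairs)."""
        return len(self.barcodes) * len(self.index_pairs)

    def assign(self, prefix: str) -> str | None:
        """The unique barcode within max_mismatch of the prefix, else None."""
        for b in self.barcodes:
            if hamming(prefix, b) <= self.max_mismatch:
                return b
        return None


def demultiplex(
    pairs: list[ReadPair], barcode_set: BarcodeSet
) -> tuple[dict[str, list[ReadPair]], pd.Series]:
    """Split read pairs by in-line barcode; the barcode is removed from R1.

    Returns (barcode -> pairs, counts) where counts includes "unassigned" and
    sums to the input pair count.
    """
    L = BARCODE_LENGTH
    out: dict[str, list[ReadPair]] = {b: [] for b in barcode_set.barcodes}
    counts = {b: 0 for b in barcode_set.barcodes}
    counts["unassigned"] = 0
    for p in pairs:
        if len(p.r1) < L:
            counts["unassigned"] += 1
            continue
        b = barcode_set.assign(p.r1[:L])
        if b is None:
            counts["unassigned"] += 1
        else:
            out[b].append(ReadPair(p.read_id, p.r1[L:], p.r2))
            counts[b] += 1
    return out, pd.Series(counts, name="pairs")


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

@dataclass
class TrimPolicy:
    """Trimming parameters; the 16 bp fixed end-trims are the historical
    single-nucleus defaults, with tail detection layered on top."""

    fixed_5p_r1: int = 16
    fixed_3p_r1: int = 16
    fixed_5p_r2: int = 16
    fixed_3p_r2: int = 16
    r2_extra_5p: int = 0
    adapter_r1: str = ADAPTER_R1
    adapter_r2: str = ADAPTER_R2
    min_insert: int = 30
    tail_detect: bool = True
    tail_alphabet: tuple[str, ...] = ("A", "G")
    tail_max: int = 50

    def validate(self) -> None:
        for v, what in [
            (self.fixed_5p_r1, "fixed_5p_r1"), (self.fixed_3p_r1, "fixed_3p_r1"),
            (self.fixed_5p_r2, "fixed_5p_r2"), (self.fixed_3p_r2, "fixed_3p_r2"),
            (self.r2_extra_5p, "r2_extra_5p"), (self.tail_max, "tail_max"),
        ]:
            if v < 0:
                raise ValueError(f"{what} must be >= 0")
        if self.min_insert < 1:
            raise ValueError("min_insert must be >= 1")


@dataclass
class TrimResult:
    r1: str
    r2: str
    klass: str          # "keep" or "dimer_or_short"
    tail_len: int


def detect_tail(r2: str, alphabet, tail_max: int) -> int:
    """First-exit tail detector: length of the longest prefix made only of
    alphabet bases, capped at tail_max."""
    allowed = set(alphabet)
    cap = min(tail_max, len(r2))
    for i in range(cap):
        if r2[i] not in allowed:
            return i
    return cap


def trim_adapter(seq: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove a 3' read-through adapter by exact seed match, then by
    suffix-prefix overlap of at least min_overlap bases."""
    seed = adapter[:12]
    j = seq.find(seed)
    if j >= 0:
        return seq[:j]
    for olen in range(min(len(adapter), len(seq), 11), min_overlap - 1, -1):
        if seq.endswith(adapter[:olen]):
            return seq[: len(seq) - olen]
    return seq


def trim_pair(r1: str, r2: str, policy: TrimPolicy) -> TrimResult:
    """Tail-detect, adapter-trim and end-trim one pair, then classify it.

    Classification uses the trimmed R1 length as the insert proxy (R1 carries
    no Adaptase tail): a pair whose R1 retains fewer than ``min_insert`` bases
    is an adapter dimer or short insert. Trimming never yields negative
    lengths and never lengthens a read.
    """
    policy.validate()
    if not r1 or not r2:
        return TrimResult("", "", "dimer_or_short", 0)
    tail_len = 0
    if policy.tail_detect:
        tail_len = detect_tail(r2, policy.tail_alphabet, policy.tail_max)
        r2 = r2[tail_len:]
    r1 = trim_adapter(r1, policy.adapter_r1)
    r2 = trim_adapter(r2, policy.adapter_r2)
    r1 = r1[policy.fixed_5p_r1 : max(policy.fixed_5p_r1, len(r1) - policy.fixed_3p_r1)]
    cut5 = policy.fixed_5p_r2 + policy.r2_extra_5p
    r2 = r2[cut5 : max(cut5, len(r2) - policy.fixed_3p_r2)]
    klass = "keep" if len(r1) >= policy.min_insert else "dimer_or_short"
    return TrimResult(r1, r2, klass, tail_len)


def trim_pairs(
    pairs: list[ReadPair], policy: TrimPolicy
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Trim a batch; returns kept pairs and a per-read report."""
    kept, rows = [], []
    for p in pairs:
        res = trim_pair(p.r1, p.r2, policy)
        rows.append(
            {"read_id": p.read_id, "klass": res.klass, "tail_len": res.tail_len,
             "r1_len": len(res.r1), "r2_len": len(res.r2)}
        )
        if res.klass == "keep":
            kept.append(ReadPair(p.read_id, res.r1, res.r2))
    return kept, pd.DataFrame(rows)


def tail_length_summary(
    pairs: list[ReadPair], policy: TrimPolicy
) -> dict[str, float]:
    """Raw and bias-corrected mean detected tail length over a batch.

    The correction subtracts the expected geometric overshoot q/(1-q) of the
    first-exit detector, with q estimated as the in-alphabet base rate at read
    positions past ``tail_max`` (which are never tail).
    """
    allowed = set(policy.tail_alphabet)
    lens, n_exit = [], 0
    in_alpha = total = 0
    for p in pairs:
        t = detect_tail(p.r2, policy.tail_alphabet, policy.tail_max)
        lens.append(t)
        if t < min(policy.tail_max, len(p.r2)):
            n_exit += 1
        post = p.r2[policy.tail_max : policy.tail_max + 20]
        in_alpha += sum(b in allowed for b in post)
        total += len(post)
    raw = float(np.mean(lens)) if lens else float("nan")
    q = in_alpha / total if total else 0.0
    overshoot = q / (1.0 - q) if q < 1.0 else float("nan")
    corrected = raw - overshoot * (n_exit / len(lens)) if lens else float("nan")
    return {
        "raw_mean": raw,
        "corrected_mean": corrected,
        "q_hat": q,
        "n": len(lens),
    }


# ---------------------------------------------------------------------------
# Base composition diagnostics
# ---------------------------------------------------------------------------

def composition_profile(reads: list[str], positions: int) -> pd.DataFrame:
    """Exact per-position base frequencies over a read set.

    Reads shorter than a position are excluded from that position's
    denominator. Returns one row per position (1-based) with A/C/G/T/N
    frequencies and the denominator n.
    """
    if positions < 1:
        raise ValueError("positions must be >= 1")
    counts = np.zeros((positions, 5), dtype=np.int64)
    bases = "ACGTN"
    idx = {b: i for i, b in enumerate(bases)}
    for r in reads:
        for j in range(min(positions, len(r))):
            counts[j, idx.get(r[j], 4)] += 1
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / n[:, None]
    df = pd.DataFrame(freq, columns=list(bases))
    df.insert(0, "position", np.arange(1, positions + 1))
    df["n"] = n
    df.attrs["empty"] = bool((n == 0).all())
    return df


def expected_composition(
    f_c: float, f_t: float, mbar: float, conversion_rate: float
) -> tuple[float, float]:
    """Post-bisulfite expectations for the C->T-signature read.

    expected_c: a genomic C reads as C only if methylated or unconverted;
    expected_t: genomic T plus converted unmethylated C.
    """
    expected_c = f_c * (mbar + (1.0 - mbar) * (1.0 - conversion_rate))
    expected_t = f_t + f_c * (1.0 - mbar) * conversion_rate
    return expected_c, expected_t


def genome_base_fractions(genome: Genome) -> dict[str, float]:
    """Single-strand base fractions of the genome, averaged over strands
    (so f_c == f_g and f_a == f_t by symmetry)."""
    from ._seqops import A, C, G, T

    counts = {b: 0 for b in "ACGT"}
    n = 0
    for name in genome.genomic_names():
        arr = genome.arr(name)
        counts["A"] += int((arr == A).sum())
        counts["C"] += int((arr == C).sum())
        counts["G"] += int((arr == G).sum())
        counts["T"] += int((arr == T).sum())
        n += len(arr)
    fa = (counts["A"] + counts["T"]) / (2 * n)
    fc = (counts["C"] + counts["G"]) / (2 * n)
    return {"A": fa, "C": fc, "G": fc, "T": fa}


def expected_composition_from_truth(
    genome: Genome, truth: MethylomeTruth, conversion_rate: float
) -> tuple[float, float]:
    f = genome_base_fractions(genome)
    mbar = truth.mean_cytosine_methylation()
    return expected_composition(f["C"], f["T"], mbar, conversion_rate)


def flag_composition_anomaly(
    profile: pd.DataFrame, expected_c: float, n_positions: int = 10,
    margin: float = 0.02,
) -> bool:
    """True when the max C frequency over the first read positions exceeds the
    post-bisulfite expectation by more than the margin (the dNTP-carryover
    signature at R2 starts)."""
    head = profile.iloc[:n_positions]
    return bool((head["C"].max() or 0.0) > expected_c + margin)
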