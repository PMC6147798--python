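"""Lightweight three-letter bisulfite alignment for desk-scale genomes.

Bisulfite conversion collapses the read alphabet: the C-depleted template
sense (R2 here) is compared under C->T, the complementary sense (R1) under
G->A. Each read is therefore searched in four (conversion x orientation)
combinations against two converted reference frames:

* ``CT`` frame: Watson with C->T — hits report Watson-strand cytosines;
* ``GA`` frame: Watson with G->A — hits report Crick-strand cytosines.

Alignment is exact k-mer seeding plus ungapped extension (the simulator emits
no indels); the score is matches minus mismatches and hits above a 10%
mismatch fraction are rejected. MAPQ is min(60, 2*(best - second_best)) with
second_best = 0 for a unique locus; ties score MAPQ 0 and are removed by the
standard MAPQ > 10 filter.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seqops import (
    array_to_seq,
    convert_ct,
    convert_ga,
    revcomp,
    revcomp_array,
    seq_to_array,
)
from .genome import Genome, ReadPair

DEFAULT_K = 16
DEFAULT_MAPQ_MIN = 10


@dataclass
class AlignmentHit:
    read_id: str
    mate: int                 # 1 or 2
    contig: str
    start: int                # 0-based Watson coordinate
    length: int
    frame: str                # "CT" (Watson cytosines) or "GA" (Crick)
    orientation: str          # "fwd"/"rev" relative to Watson
    score: int                # matches - mismatches
    n_mismatch: int
    mapq: int
    seq_fwd: str              # unconverted read, Watson-forward orientation
    cell: str = ""


class ConvertedIndex:
    """Exact k-mer index over the two converted reference frames."""

    def __init__(self, genome: Genome, k: int = DEFAULT_K):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.genome = genome
        self.k = k
        self.names = genome.names
        self.refs: dict[str, dict[str, np.ndarray]] = {"CT": {}, "GA": {}}
        self.index: dict[str, dict[bytes, list[tuple[int, int]]]] = {
            "CT": defaultdict(list),
            "GA": defaultdict(list),
        }
        for ci, name in enumerate(self.names):
            arr = genome.arr(name)
            for frame, conv in (("CT", convert_ct), ("GA", convert_ga)):
                ref = conv(arr)
                self.refs[frame][name] = ref
                buf = ref.tobytes()
                idx = self.index[frame]
                for p in range(0, len(buf) - k + 1):
                    idx[buf[p : p + k]].append((ci, p))


def _query_combos(read: str, mate: int | None):
    """(query array, frame, orientation) combinations valid for the mate.

    R2 carries the C->T signature: forward against the CT frame (Watson
    origin) or reverse-complemented against the GA frame (Crick origin).
    R1 carries the G->A signature: the mirrored pair of combinations.
    """
    arr = seq_to_array(read)
    combos = []
    if mate in (2, None):
        ct = convert_ct(arr)
        combos.append((ct, "CT", "fwd"))
        combos.append((revcomp_array(ct), "GA", "rev"))
    if mate in (1, None):
        ga = convert_ga(arr)
        combos.append((revcomp_array(ga), "CT", "rev"))
        combos.append((ga, "GA", "fwd"))
    return combos


def align_read(
    read: str,
    index: ConvertedIndex,
    read_id: str = "",
    mate: int | None = None,
    seed_step: int = 5,
    max_mismatch_frac: float = 0.1,
) -> AlignmentHit | None:
    """Best ungapped hit of one read, or None when no seed anchors it."""
    k = index.k
    L = len(read)
    if L < k:
        return None

    candidates: set[tuple[str, str, int, int]] = set()  # (frame, orient) keyed
    queries: dict[tuple[str, str], np.ndarray] = {}
    for q, frame, orient in _query_combos(read, mate):
        queries[(frame, orient)] = q
        buf = q.tobytes()
        offsets = list(range(0, L - k + 1, seed_step))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        idx = index.index[frame]
        for o in offsets:
            for ci, p in idx.get(buf[o : o + k], ()):
                start = p - o
                candidates.add((frame, orient, ci, start))

    max_mm = int(max_mismatch_frac * L)
    best = second_score = None
    for frame, orient, ci, start in candidates:
        name = index.names[ci]
        ref = index.refs[frame][name]
        if start < 0 or start + L > len(ref):
            continue
        q = queries[(frame, orient)]
        mm = int(np.count_nonzero(ref[start : start + L] != q))
        if mm > max_mm:
            continue
        score = L - 2 * mm
        if best is None or score > best[0]:
            second_score = None if best is None else best[0]
            best = (score, mm, frame, orient, name, start)
        elif second_score is None or score > second_score:
            second_score = score

    if best is None:
        return None
    score, mm, frame, orient, name, start = best
    if second_score is None:
        mapq = min(60, 2 * score)
    else:
        mapq = max(0, min(60, 2 * (score - second_score)))
    seq_fwd = read if orient == "fwd" else revcomp(read)
    return AlignmentHit(
        read_id=read_id, mate=mate or 0, contig=name, start=start, length=L,
        frame=frame, orientation=orient, score=score, n_mismatch=mm,
        mapq=mapq, seq_fwd=seq_fwd,
    )


def align_pairs(
    pairs: list[ReadPair],
    index: ConvertedIndex,
    cell: str = "",
    seed_step: int = 5,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[AlignmentHit], dict[str, int]]:
    """Align both mates of every pair; returns hits and per-mate counts."""
    hits: list[AlignmentHit] = []
    counts = {"input_r1": 0, "input_r2": 0, "mapped_r1": 0, "mapped_r2": 0}
    for p in pairs:
        for mate, seq in ((1, p.r1), (2, p.r2)):
            if not seq:
                continue
            counts[f"input_r{mate}"] += 1
            h = align_read(
                seq, index, read_id=p.read_id, mate=mate,
                seed_step=seed_step, max_mismatch_frac=max_mismatch_frac,
            )
            if h is not None:
                h.cell = cell
                hits.append(h)
                counts[f"mapped_r{mate}"] += 1
    return hits, counts


def filter_alignments(
    hits: list[AlignmentHit], mapq_min: int = DEFAULT_MAPQ_MIN
) -> list[AlignmentHit]:
    """Strict MAPQ filter (mapq > mapq_min) followed by clonal collapse.

    Clonal reads — same (cell, contig, start, frame) — are PCR duplicates and
    collapse to the highest-scoring representative.
    """
    passing = [h for h in hits if h.mapq > mapq_min]
    best: dict[tuple, AlignmentHit] = {}
    for h in passing:
        key = (h.cell, h.contig, h.start, h.frame)
        cur = best.get(key)
        if cur is None or h.score > cur.score:
            best[key] = h
    return list(best.values())


def mapping_rate(counts: dict[str, int]) -> dict[str, float | None]:
    """Per-mate and combined mapped/input fractions; None on zero input."""
    out: dict[str, float | None] = {}
    for mate in ("r1", "r2"):
        n = counts.get(f"input_{mate}", 0)
        out[mate] = counts.get(f"mapped_{mate}", 0) / n if n else None
    n = counts.get("input_r1", 0) + counts.get("input_r2", 0)
    m = counts.get("mapped_r1", 0) + counts.get("mapped_r2", 0)
    out["combined"] = m / n if n else None
    return out


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id, "mate": h.mate, "cell": h.cell,
                "contig": h.contig, "start": h.start, "length": h.length,
                "frame": h.frame, "orientation": h.orientation,
                "score": h.score, "n_mismatch": h.n_mismatch, "mapq": h.mapq,
            }
            for h in hits
        ]
    )


def write_sam(hits: list[AlignmentHit], genome: Genome, path) -> None:
    """Minimal SAM export (mandatory columns, MAPQ populated)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": l} for n, l in genome.lengths.items()],
    }
    tid = {n: i for i, n in enumerate(genome.lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in hits:
            a = pysam.AlignedSegment()
            a.query_name = h.read_id
            a.query_sequence = h.seq_fwd
            a.flag = (0x40 if h.mate == 1 else 0x80) | (
                0x10 if h.orientation == "rev" else 0
            )
            a.reference_id = tid[h.contig]
            a.reference_start = h.start
            a.mapping_quality = h.mapq
            a.cigarstring = f"{h.length}M"
            a.set_tag("NM", h.n_mismatch)
            a.set_tag("ZF", h.frame)
            if h.cell:
                a.set_tag("RG", h.cell)
            out.write(a)
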