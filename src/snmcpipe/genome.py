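"""Genome container, cytosine catalog, and FASTA/BED input-output.

The catalog enumerates every callable cytosine on both strands (Watson ``C``
sites on ``+``, Watson ``G`` sites — i.e. Crick cytosines — on ``-``) together
with its trinucleotide context, collapsed downstream into the two classes that
matter for neuronal methylomes: CG and CH (H = A, C or T). Sites whose
trinucleotide context runs off the contig or contains N are uncallable and are
excluded from the catalog entirely.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seqops import A, C, G, T, array_to_seq, revcomp, seq_to_array


class Genome:
    """An in-memory reference genome (small, desk-scale contigs)."""

    def __init__(self, contigs: dict[str, str], lambda_contig: str | None = None):
        self.contigs: dict[str, str] = {n: s.upper() for n, s in contigs.items()}
        if lambda_contig is not None and lambda_contig not in self.contigs:
            raise ValueError(f"lambda contig {lambda_contig!r} not in genome")
        self.lambda_contig = lambda_contig
        self._arrays: dict[str, np.ndarray] = {}

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.contigs.items()}

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def arr(self, name: str) -> np.ndarray:
        if name not in self._arrays:
            self._arrays[name] = seq_to_array(self.contigs[name])
        return self._arrays[name]

    def genomic_names(self) -> list[str]:
        """Contig names excluding the spike-in contig."""
        return [n for n in self.contigs if n != self.lambda_contig]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=n, description="") for n, s in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, lambda_contig: str | None = None) -> "Genome":
        contigs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(contigs, lambda_contig=lambda_contig)


@dataclass
class ContigCatalog:
    """Callable cytosines of one contig, both strands, Watson coordinates."""

    pos: np.ndarray        # 0-based Watson coordinate of the cytosine
    watson: np.ndarray     # bool: True => '+' strand (Watson C), False => '-'
    cg: np.ndarray         # bool: CG context class (else CH)
    context: np.ndarray    # 'U3' trinucleotide on the cytosine's own strand
    plus_map: np.ndarray   # int32, length = contig; Watson pos -> row or -1
    minus_map: np.ndarray  # int32; Watson pos of a Watson G -> row or -1

    @property
    def n(self) -> int:
        return len(self.pos)


class CytosineCatalog:
    def __init__(self, per_contig: dict[str, ContigCatalog]):
        self.per_contig = per_contig

    def __getitem__(self, name: str) -> ContigCatalog:
        return self.per_contig[name]

    def __contains__(self, name: str) -> bool:
        return name in self.per_contig

    def n_sites(self, name: str) -> int:
        return self.per_contig[name].n


def build_cytosine_catalog(genome: Genome) -> CytosineCatalog:
    per_contig = {}
    for name, seq in genome.contigs.items():
        arr = genome.arr(name)
        n = len(arr)
        rows_pos, rows_watson, rows_cg, rows_ctx = [], [], [], []
        plus_map = np.full(n, -1, dtype=np.int32)
        minus_map = np.full(n, -1, dtype=np.int32)

        c_pos = np.nonzero(arr == C)[0]
        for p in c_pos:
            if p + 2 >= n:
                continue
            ctx = seq[p : p + 3]
            if "N" in ctx:
                continue
            plus_map[p] = len(rows_pos)
            rows_pos.append(p)
            rows_watson.append(True)
            rows_cg.append(ctx[1] == "G")
            rows_ctx.append(ctx)

        g_pos = np.nonzero(arr == G)[0]
        for p in g_pos:
            if p - 2 < 0:
                continue
            ctx = revcomp(seq[p - 2 : p + 1])  # 5'->3' on the Crick strand
            if "N" in ctx:
                continue
            minus_map[p] = len(rows_pos)
            rows_pos.append(p)
            rows_watson.append(False)
            rows_cg.append(ctx[1] == "G")
            rows_ctx.append(ctx)

        per_contig[name] = ContigCatalog(
            pos=np.asarray(rows_pos, dtype=np.int64),
            watson=np.asarray(rows_watson, dtype=bool),
            cg=np.asarray(rows_cg, dtype=bool),
            context=np.asarray(rows_ctx, dtype="U3"),
            plus_map=plus_map,
            minus_map=minus_map,
        )
    return CytosineCatalog(per_contig)


# ---------------------------------------------------------------------------
# Interval sets (BED6, 0-based half-open) as plain DataFrames
# ---------------------------------------------------------------------------

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def make_intervals(rows, extra_cols: dict | None = None) -> pd.DataFrame:
    """Build an interval table from (contig, start, end, name) tuples."""
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "name"])
    if extra_cols:
        for k, v in extra_cols.items():
            df[k] = v
    return df


def validate_intervals(intervals: pd.DataFrame, genome: Genome, what: str = "interval") -> None:
    lengths = genome.lengths
    for row in intervals.itertuples(index=False):
        if row.contig not in lengths:
            raise ValueError(
                f"{what} {row.name!r} ({row.contig}:{row.start}-{row.end}) "
                f"references unknown contig {row.contig!r}"
            )
        if not (0 <= row.start < row.end <= lengths[row.contig]):
            raise ValueError(
                f"{what} {row.name!r} ({row.contig}:{row.start}-{row.end}) "
                f"lies outside contig {row.contig!r} (length {lengths[row.contig]})"
            )


def write_bed(intervals: pd.DataFrame, path) -> None:
    df = intervals.copy()
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "+"
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def interval_mask(length: int, intervals: pd.DataFrame, contig: str) -> np.ndarray:
    """Boolean per-position mask of a contig covered by an interval set."""
    mask = np.zeros(length, dtype=bool)
    sub = intervals[intervals["contig"] == contig]
    for row in sub.itertuples(index=False):
        mask[row.start : row.end] = True
    return mask


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    read_id: str
    r1: str
    r2: str


def write_fastq_pair(pairs, r1_path, r2_path, quality_char: str = "F") -> None:
    """Write mates to gzipped FASTQ; byte-identical across runs (mtime=0)."""
    with open(r1_path, "wb") as f1, open(r2_path, "wb") as f2:
        gz1 = gzip.GzipFile(fileobj=f1, mode="wb", mtime=0)
        gz2 = gzip.GzipFile(fileobj=f2, mode="wb", mtime=0)
        for p in pairs:
            gz1.write(
                f"@{p.read_id}/1\n{p.r1}\n+\n{quality_char * len(p.r1)}\n".encode()
            )
            gz2.write(
                f"@{p.read_id}/2\n{p.r2}\n+\n{quality_char * len(p.r2)}\n".encode()
            )
        gz1.close()
        gz2.close()


def read_fastq_pair(r1_path, r2_path) -> list[ReadPair]:
    import pysam

    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            n1 = e1.name[:-2] if e1.name.endswith("/1") else e1.name
            n2 = e2.name[:-2] if e2.name.endswith("/2") else e2.name
            if n1 != n2:
                raise ValueError(f"mate name mismatch: {e1.name} vs {e2.name}")
            pairs.append(ReadPair(n1, e1.sequence.upper(), e2.sequence.upper()))
    return pairs
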