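"""Low-level sequence helpers shared across the pipeline.

Sequences are plain upper-case ACGTN strings; hot paths work on uint8 numpy
arrays (ASCII codes) to keep the pure-Python aligner fast enough for
desk-scale genomes.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# ASCII codes
A, C, G, T, N = (ord(b) for b in "ACGTN")

_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_x] = _y

_CT_TABLE = np.arange(256, dtype=np.uint8)
_CT_TABLE[C] = T
_GA_TABLE = np.arange(256, dtype=np.uint8)
_GA_TABLE[G] = A


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]


def convert_ct(arr: np.ndarray) -> np.ndarray:
    """Bisulfite frame conversion C->T."""
    return _CT_TABLE[arr]


def convert_ga(arr: np.ndarray) -> np.ndarray:
    """Bisulfite frame conversion G->A."""
    return _GA_TABLE[arr]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
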