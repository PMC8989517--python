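"""Low-level nucleotide sequence helpers shared across the toolkit.

Sequences are plain Python ``str`` over the alphabet {A, C, G, T} at the
API surface; internally most operations run on ``numpy`` uint8 arrays of
ASCII codes (fast, zero-copy via ``frombuffer``).
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# ASCII codes for the four bases, index order A,C,G,T
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# uint8 ASCII -> 2-bit code (A=0, C=1, G=2, T=3); 255 marks non-ACGT
_ASCII_TO_BITS = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ASCII_TO_BITS[_c] = _i

# ASCII complement table for uint8 arrays
_ASCII_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _ASCII_COMP[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """ASCII uint8 view of a sequence (no copy)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _ASCII_COMP[arr][::-1]


def random_bases(n: int, gc_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. ASCII bases with the requested GC content."""
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    cumulative = np.cumsum([at, gc, gc, at])  # A, C, G, T
    idx = np.searchsorted(cumulative, rng.random(n), side="right").clip(0, 3)
    return BASES[idx]


def gc_content(seq: str) -> float:
    arr = seq_to_array(seq)
    return float(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))) / len(arr))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed integer codes of all k-mers of an ASCII uint8 array.

    Returns an int64 array of length ``len(arr) - k + 1`` (empty if the
    sequence is shorter than k).  Assumes pure ACGT input.
    """
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    bits = _ASCII_TO_BITS[arr].astype(np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        out += bits[j : n - k + 1 + j] << (2 * (k - 1 - j))
    return out


def mutate_guide(guide: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """A copy of ``guide`` with exactly ``n_mismatches`` substituted positions."""
    arr = seq_to_array(guide).copy()
    positions = rng.choice(len(arr), size=n_mismatches, replace=False)
    for p in positions:
        current = arr[p]
        choices = BASES[BASES != current]
        arr[p] = rng.choice(choices)
    return array_to_seq(arr)


def hamming(a: str, b: str) -> int:
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))
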