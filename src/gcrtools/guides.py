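"""Genome-wide enumeration of CRISPR guide matching sites.

Every 20-bp window on either strand whose Hamming distance to the guide is
at most ``max_mismatch`` (0, 1 or 2) is reported, optionally restricted to
windows followed 3' (strand-aware) by an NGG PAM.  This reproduces a raw
sequence-census style of site counting ("report all alignments", no PAM
model) as used to size multi-target guide libraries; PAM filtering is an
option for modelling actual cleavage.

The production scan is a chunked, vectorised sliding-window comparison; its
contract is exact set equality with a naive per-window Hamming oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .errors import SpecificationError
from .sequtils import revcomp, seq_to_array
from .synthetic import Genome

_CHUNK = 1 << 20  # bases per scan chunk; bounds peak memory at ~20 MB


@dataclass(frozen=True)
class GuideMatch:
    """One protospacer match.

    ``protospacer_start`` is the leftmost base of the 20-bp window in
    forward-strand coordinates regardless of strand; ``matched_sequence``
    is reported in protospacer orientation (reverse-complemented for
    minus-strand matches).
    """

    chrom: str
    protospacer_start: int
    strand: str
    mismatch_count: int
    matched_sequence: str


def _validate_guide(guide: str) -> None:
    if len(guide) != 20:
        raise SpecificationError("guide must be exactly 20 nt")
    if any(b not in "ACGT" for b in guide):
        raise SpecificationError("guide must be over {A,C,G,T}")


def _scan_strand(
    arr: np.ndarray, pattern: np.ndarray, max_mismatch: int
) -> np.ndarray:
    """Window start positions with Hamming distance <= max_mismatch, plus
    the distances, as an (n, 2) int array.  Chunked to bound memory."""
    k = len(pattern)
    n = len(arr)
    if n < k:
        return np.empty((0, 2), dtype=np.int64)
    hits = []
    for lo in range(0, n - k + 1, _CHUNK):
        hi = min(lo + _CHUNK + k - 1, n)
        windows = np.lib.stride_tricks.sliding_window_view(arr[lo:hi], k)
        mism = (windows != pattern).sum(axis=1)
        idx = np.flatnonzero(mism <= max_mismatch)
        if len(idx):
            hits.append(np.column_stack([idx + lo, mism[idx]]))
    if not hits:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(hits).astype(np.int64)


def _pam_ok_forward(arr: np.ndarray, pos: np.ndarray, k: int) -> np.ndarray:
    """NGG immediately 3' of a forward-strand protospacer."""
    n = len(arr)
    ok = (pos + k + 3) <= n  # needs bases at pos+k .. pos+k+2
    g = ord("G")
    valid = np.zeros(len(pos), dtype=bool)
    in_range = np.flatnonzero(ok)
    p = pos[in_range]
    valid[in_range] = (arr[p + k + 1] == g) & (arr[p + k + 2] == g)
    return valid


def _pam_ok_reverse(arr: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """NGG 3' of a minus-strand protospacer = CCN ending just left of it."""
    c = ord("C")
    valid = np.zeros(len(pos), dtype=bool)
    in_range = np.flatnonzero(pos >= 3)
    p = pos[in_range]
    valid[in_range] = (arr[p - 3] == c) & (arr[p - 2] == c)
    return valid


def find_guide_matches(
    genome: Genome,
    guide: str,
    max_mismatch: int = 0,
    require_pam: bool = False,
    pam_pattern: str = "NGG",
) -> List[GuideMatch]:
    """All <=max_mismatch matches of a 20-nt guide on both strands.

    Sorted by (chrom, position, strand); overlapping matches are all
    reported.  Only the canonical NGG PAM is supported when
    ``require_pam`` is set.
    """
    _validate_guide(guide)
    if max_mismatch not in (0, 1, 2):
        raise SpecificationError("max_mismatch must be 0, 1 or 2")
    if require_pam and pam_pattern != "NGG":
        raise SpecificationError("only the NGG PAM pattern is supported")
    fwd = seq_to_array(guide)
    rev = seq_to_array(revcomp(guide))
    matches: List[GuideMatch] = []
    for chrom, seq in genome.chromosomes.items():
        arr = seq_to_array(seq)
        per_pos: Dict[int, List[GuideMatch]] = {}
        f_hits = _scan_strand(arr, fwd, max_mismatch)
        if len(f_hits) and require_pam:
            keep = _pam_ok_forward(arr, f_hits[:, 0], 20)
            f_hits = f_hits[keep]
        for pos, mm in f_hits:
            window = seq[pos : pos + 20]
            per_pos.setdefault(int(pos), []).append(
                GuideMatch(chrom, int(pos), "+", int(mm), window)
            )
        # a minus-strand protospacer at forward window p satisfies
        # window == revcomp(guide)
        r_hits = _scan_strand(arr, rev, max_mismatch)
        if len(r_hits) and require_pam:
            keep = _pam_ok_reverse(arr, r_hits[:, 0])
            r_hits = r_hits[keep]
        for pos, mm in r_hits:
            window = seq[pos : pos + 20]
            per_pos.setdefault(int(pos), []).append(
                GuideMatch(chrom, int(pos), "-", int(mm), revcomp(window))
            )
        for pos in sorted(per_pos):
            matches.extend(sorted(per_pos[pos], key=lambda m: m.strand))
    return matches


def matches_to_table(matches: List[GuideMatch]):
    """BED6-compatible table: chrom, start, end, strand, mismatches, sequence."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in matches],
            "start": [m.protospacer_start for m in matches],
            "end": [m.protospacer_start + 20 for m in matches],
            "strand": [m.strand for m in matches],
            "mismatches": [m.mismatch_count for m in matches],
            "sequence": [m.matched_sequence for m in matches],
        }
    )
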