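"""Binned copy-number analysis: sample-vs-control differencing, high-CNV
region calling, cross-sample correlation and interval coverage ratios.

The CNV statistic is deliberately simple, mirroring read-match differencing
over a fixed genome grid (500 kb bins at human scale, scaled down for
synthetic genomes): per-bin value = normalized_count(sample) −
normalized_count(control).  No segmentation model is applied; "high CNV"
bins are called by a scale-free absolute-quantile rule (or an absolute
z-score rule) and merged into regions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Tuple

import numpy as np
from scipy import stats

from .errors import DataError, SpecificationError, UndefinedRatioError
from .synthetic import BinnedCounts


@dataclass
class CNVProfile:
    """Per-bin normalized count difference between a sample pair."""

    sample_pair: str
    bin_size: int
    values: Dict[str, np.ndarray]  # chrom -> float array per bin
    chrom_lengths: Dict[str, int]

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.values.values())

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.values])

    def bins(self) -> List[Tuple[str, int, int]]:
        out = []
        for chrom, vals in self.values.items():
            length = self.chrom_lengths[chrom]
            for i in range(len(vals)):
                out.append((chrom, i * self.bin_size,
                            min((i + 1) * self.bin_size, length)))
        return out

    def same_grid(self, other: "CNVProfile") -> bool:
        return (self.bin_size == other.bin_size
                and self.chrom_lengths == other.chrom_lengths
                and list(self.values) == list(other.values))


@dataclass
class RegionSet:
    """Merged, sorted, non-overlapping genomic intervals (0-based half-open)."""

    intervals: List[Tuple[str, int, int]]

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def merge_intervals(intervals) -> List[Tuple[str, int, int]]:
    out: List[Tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if s >= e:
            raise DataError(f"empty interval {chrom}:{s}-{e}")
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


@dataclass(frozen=True)
class CorrelationReport:
    level: str  # per_bin | per_chromosome
    r_squared: float
    slope: float
    intercept: float
    n_points: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def cnv_difference(
    counts_sample: BinnedCounts,
    counts_control: BinnedCounts,
    normalization: Literal["total_count", "none"] = "total_count",
) -> CNVProfile:
    """Per-bin count difference sample − control on a shared grid.

    With ``total_count`` normalization each sample's counts are scaled to
    the mean of the two library sizes before subtraction, making the
    profile invariant to sequencing depth differences.
    """
    if not counts_sample.same_grid(counts_control):
        raise DataError("count tables are on different bin grids")
    if normalization not in ("total_count", "none"):
        raise SpecificationError(f"unknown normalization {normalization!r}")
    if normalization == "total_count":
        target = 0.5 * (counts_sample.total_count + counts_control.total_count)
        fs = target / counts_sample.total_count if counts_sample.total_count else 1.0
        fc = target / counts_control.total_count if counts_control.total_count else 1.0
    else:
        fs = fc = 1.0
    values = {
        chrom: counts_sample.counts[chrom] * fs - counts_control.counts[chrom] * fc
        for chrom in counts_sample.counts
    }
    return CNVProfile(
        sample_pair=f"{counts_sample.sample_id}-vs-{counts_control.sample_id}",
        bin_size=counts_sample.bin_size,
        values=values,
        chrom_lengths=dict(counts_sample.chrom_lengths),
    )


def high_cnv_regions(
    profile: CNVProfile,
    rule: str = "abs_quantile",
    q: float = 0.95,
    t: float = 2.0,
) -> RegionSet:
    """Bins whose |value| exceeds a threshold, merged into regions.

    ``abs_quantile``: the threshold is the q-quantile of |value| across all
    bins (strict exceedance, so a flat profile yields no regions).
    ``abs_z``: bins with |value − mean| / sd > t; a zero-variance profile
    yields no regions.
    """
    if profile.n_bins == 0:
        raise DataError("empty profile")
    flat = profile.flat()
    if rule == "abs_quantile":
        if not 0.0 < q < 1.0:
            raise SpecificationError("q must lie in (0, 1)")
        threshold = float(np.quantile(np.abs(flat), q))
        exceeds = {c: np.abs(v) > threshold for c, v in profile.values.items()}
    elif rule == "abs_z":
        if t <= 0:
            raise SpecificationError("t must be positive")
        mu, sd = float(flat.mean()), float(flat.std())
        if sd == 0:
            exceeds = {c: np.zeros(len(v), dtype=bool)
                       for c, v in profile.values.items()}
        else:
            exceeds = {c: np.abs(v - mu) / sd > t
                       for c, v in profile.values.items()}
    else:
        raise SpecificationError(f"unknown rule {rule!r}")
    intervals = []
    for chrom, mask in exceeds.items():
        length = profile.chrom_lengths[chrom]
        idx = np.flatnonzero(mask)
        for i in idx:
            intervals.append((chrom, int(i) * profile.bin_size,
                              min((int(i) + 1) * profile.bin_size, length)))
    return RegionSet(intervals)


def common_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Base-pair intersection of two region sets."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in b:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for chrom, s, e in a:
        for s2, e2 in by_chrom.get(chrom, []):
            lo, hi = max(s, s2), min(e, e2)
            if lo < hi:
                out.append((chrom, lo, hi))
    return RegionSet(out)


def cnv_correlation(
    p1: CNVProfile,
    p2: CNVProfile,
    level: Literal["per_bin", "per_chromosome"] = "per_bin",
) -> CorrelationReport:
    """Least-squares fit of one CNV profile against another.

    ``per_chromosome`` fits the per-chromosome sums of the profiles,
    capturing chromosome-scale gain/loss concordance.
    """
    if not p1.same_grid(p2):
        raise DataError("profiles are on different bin grids")
    if level == "per_bin":
        x, y = p1.flat(), p2.flat()
    elif level == "per_chromosome":
        x = np.array([p1.values[c].sum() for c in p1.values])
        y = np.array([p2.values[c].sum() for c in p2.values])
    else:
        raise SpecificationError(f"unknown level {level!r}")
    if len(x) < 3:
        raise DataError("need at least 3 points for a correlation")
    fit = stats.linregress(x, y)
    return CorrelationReport(
        level=level,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(len(x)),
    )


def interval_coverage_ratio(
    depth: np.ndarray,
    numerator_interval: Tuple[int, int],
    denominator_interval: Tuple[int, int],
) -> float:
    """Mean depth over one interval relative to another.

    Used e.g. to quantify loss of an expression cassette's central region
    relative to an intact marker on the same construct.  ``depth`` is a
    base-resolution (or per-bin) coverage vector indexed by position.
    """
    for name, (s, e) in (("numerator", numerator_interval),
                         ("denominator", denominator_interval)):
        if not (0 <= s < e <= len(depth)):
            raise DataError(f"{name} interval [{s},{e}) not covered")
    num = float(np.mean(depth[numerator_interval[0]:numerator_interval[1]]))
    den = float(np.mean(depth[denominator_interval[0]:denominator_interval[1]]))
    if den == 0:
        raise UndefinedRatioError("denominator interval has zero coverage")
    return num / den
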