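"""Breakpoint statistics for rearranged genomes.

Three statistics defined on junction (breakpoint-pair) lists:

* permutation enrichment — are breakpoints over-represented in a region
  set (e.g. high-CNV regions)?  Regions are re-placed uniformly at random
  genome-wide (length-preserved, non-overlapping) many times; a one-sided
  upper-tail P is reported from a normal approximation to the null, with
  the empirical permutation P alongside.
* Monte-Carlo intra/inter null — are same-chromosome junctions more
  frequent than expected when both endpoints are placed uniformly
  (chromosome picked proportional to length)?  The closed form for the
  null intra fraction is sum_i (L_i / L)^2; a chi-square test with 1 df
  compares observed to simulated-expected counts.
* nearest-element distances — for every breakpoint, the distance to the
  closest repeat element of a class on the same chromosome, binned into
  the conventional distance categories.

Plus genome linearization of junctions for 2-D breakpoint plots.
"""
from __future__ import annotations

import math
import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DataError, SpecificationError
from .rearrange import Junction
from .synthetic import RepeatAnnotation

IN_ELEMENT = "in_element"
LT_1KB = "lt_1kb"
KB_1_10 = "kb_1_10"
KB_10_100 = "kb_10_100"
GT_100KB = "gt_100kb"
NO_ELEMENT = "no_element_on_chrom"

DISTANCE_CATEGORIES = (IN_ELEMENT, LT_1KB, KB_1_10, KB_10_100, GT_100KB,
                       NO_ELEMENT)


@dataclass(frozen=True)
class PermutationResult:
    observed_count: int
    n_permutations: int
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    empirical_p: float
    degenerate: bool
    seed: int


@dataclass(frozen=True)
class MCResult:
    n_events: int
    observed_intra: int
    observed_inter: int
    expected_intra_mean: float
    expected_inter_mean: float
    chi_square: float
    p_value: float
    closed_form_intra_fraction: float
    n_runs: int
    seed: int


@dataclass(frozen=True)
class DistanceRecord:
    chrom: str
    pos: int
    nearest_copy_id: Optional[str]
    element_class: Optional[str]
    distance: float  # 0 inside an element; inf when none on the chromosome
    category: str


def breakpoint_list(junctions: Sequence[Junction]) -> List[Tuple[str, int]]:
    """Both ends of every junction, as (chrom, pos) pairs."""
    out = []
    for j in junctions:
        out.append((j.chromA, j.posA))
        out.append((j.chromB, j.posB))
    return out


def _region_arrays(regions) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out[chrom] = (np.array([s for s, _ in ivs], dtype=np.int64),
                      np.array([e for _, e in ivs], dtype=np.int64))
    return out


def _points_in_regions(points: Sequence[Tuple[str, int]], arrays) -> np.ndarray:
    """Boolean membership per point."""
    inside = np.zeros(len(points), dtype=bool)
    for i, (chrom, pos) in enumerate(points):
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        inside[i] = k >= 0 and pos < ends[k]
    return inside


def count_breakpoints_in_regions(
    junctions: Sequence[Junction],
    regions,
    counting: str = "per_breakpoint",
) -> int:
    """Breakpoints (or junctions) falling inside a region set.

    ``per_breakpoint`` counts each junction end independently;
    ``per_junction`` counts a junction once when either end is inside.
    """
    arrays = _region_arrays(regions)
    if counting == "per_breakpoint":
        return int(_points_in_regions(breakpoint_list(junctions), arrays).sum())
    if counting == "per_junction":
        a = _points_in_regions([(j.chromA, j.posA) for j in junctions], arrays)
        b = _points_in_regions([(j.chromB, j.posB) for j in junctions], arrays)
        return int((a | b).sum())
    raise SpecificationError(f"unknown counting mode {counting!r}")


def _shuffle_regions(
    lengths: List[int],
    genome_sizes: Dict[str, int],
    rng: np.random.Generator,
    max_tries: int = 1000,
):
    """Length-preserved uniform re-placement without overlap among placed
    intervals (any chromosome, like a genome-wide bedtools-style shuffle)."""
    names = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in names], dtype=float)
    placed_s: Dict[str, List[int]] = {c: [] for c in names}
    placed_e: Dict[str, List[int]] = {c: [] for c in names}
    cache: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    out = []
    for length in lengths:
        if length not in cache:
            room = np.maximum(sizes - length + 1, 0)
            if room.sum() == 0:
                raise DataError(f"no chromosome can hold a {length} bp interval")
            cache[length] = (room, np.cumsum(room / room.sum()))
        room, cumw = cache[length]
        for _ in range(max_tries):
            ci = int(np.searchsorted(cumw, rng.random()))
            chrom = names[ci]
            start = int(rng.random() * room[ci])
            end = start + length
            i = bisect_left(placed_s[chrom], end)
            if i > 0 and placed_e[chrom][i - 1] > start:
                continue
            placed_s[chrom].insert(i, start)
            placed_e[chrom].insert(i, end)
            out.append((chrom, start, end))
            break
        else:
            raise DataError("shuffle placement failed; regions too dense")
    return out


def permutation_enrichment(
    junctions: Sequence[Junction],
    regions,
    genome_sizes: Dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    counting: str = "per_breakpoint",
) -> PermutationResult:
    """Permutation test for breakpoint enrichment in a region set.

    Breakpoints stay fixed; the region intervals are re-placed uniformly
    n_perm times, the overlap statistic T recomputed each time, and a
    one-sided upper P derived from the normal approximation to the null
    (empirical P reported alongside).
    """
    if n_perm < 100:
        raise SpecificationError("n_perm must be >= 100 for reporting")
    region_list = list(regions)
    total_region = sum(e - s for _, s, e in region_list)
    total_genome = sum(genome_sizes.values())
    if total_region > 0.5 * total_genome:
        warnings.warn("regions cover more than half the genome; "
                      "shuffling may be infeasible", stacklevel=2)
    observed = count_breakpoints_in_regions(junctions, region_list, counting)
    if len(junctions) == 0:
        return PermutationResult(0, n_perm, 0.0, 0.0, 0.0, 1.0, 1.0, True, seed)

    rng = np.random.default_rng(seed)
    lengths = [e - s for _, s, e in region_list]
    # per-chromosome sorted breakpoint positions, with junction ids for
    # per-junction counting
    points = breakpoint_list(junctions)
    per_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome_sizes:
        sel = [(pos, i // 2) for i, (c, pos) in enumerate(points) if c == chrom]
        sel.sort()
        per_chrom[chrom] = (np.array([p for p, _ in sel], dtype=np.int64),
                            np.array([j for _, j in sel], dtype=np.int64))
    n_junc = len(junctions)
    null = np.empty(n_perm, dtype=np.int64)
    hit = np.zeros(n_junc, dtype=bool)
    for p in range(n_perm):
        placed = _shuffle_regions(lengths, genome_sizes, rng)
        if counting == "per_breakpoint":
            t = 0
            for chrom, s, e in placed:
                pos, _ = per_chrom[chrom]
                t += int(np.searchsorted(pos, e, side="left")
                         - np.searchsorted(pos, s, side="left"))
        else:
            hit[:] = False
            for chrom, s, e in placed:
                pos, jid = per_chrom[chrom]
                lo = int(np.searchsorted(pos, s, side="left"))
                hi = int(np.searchsorted(pos, e, side="left"))
                hit[jid[lo:hi]] = True
            t = int(hit.sum())
        null[p] = t
    mu = float(null.mean())
    sd = float(null.std())
    empirical = float((1 + int((null >= observed).sum())) / (n_perm + 1))
    if sd == 0:
        return PermutationResult(observed, n_perm, mu, 0.0, 0.0, 1.0,
                                 empirical, True, seed)
    # continuity-corrected upper tail: T is a discrete count, so the
    # uncorrected normal tail is anticonservative
    z = (observed - 0.5 - mu) / sd
    p_value = float(stats.norm.sf(z))
    return PermutationResult(observed, n_perm, mu, sd, float(z), p_value,
                             empirical, False, seed)


def mc_intra_inter(
    junctions: Sequence[Junction],
    chrom_lengths: Dict[str, int],
    n_runs: int = 10,
    seed: int = 0,
    n_events: Optional[int] = None,
) -> MCResult:
    """Monte-Carlo null for the intra- vs inter-chromosomal junction split.

    Per run, as many random endpoint pairs as observed junctions are drawn
    with each endpoint uniform over the genome; the averages over n_runs
    give the expected intra/inter counts, compared to the observed split
    by a chi-square goodness-of-fit test with 1 df (no continuity
    correction).  The exact null intra fraction sum_i (L_i/L)^2 is also
    reported.
    """
    if n_events is None:
        n_events = len(junctions)
    if n_events < 1:
        raise DataError("need at least one junction")
    lengths = np.array(list(chrom_lengths.values()), dtype=float)
    w = lengths / lengths.sum()
    closed_form = float((w**2).sum())
    observed_intra = sum(1 for j in junctions if j.chromA == j.chromB)
    observed_inter = len(junctions) - observed_intra
    rng = np.random.default_rng(seed)
    a = rng.choice(len(w), size=(n_runs, n_events), p=w)
    b = rng.choice(len(w), size=(n_runs, n_events), p=w)
    intra_per_run = (a == b).sum(axis=1)
    expected_intra = float(intra_per_run.mean())
    expected_inter = float(n_events - expected_intra)
    # expected counts rescaled to the observed total (they differ only when
    # n_events is overridden for calibration experiments)
    n_obs = observed_intra + observed_inter
    f_exp = [expected_intra / n_events * n_obs,
             expected_inter / n_events * n_obs]
    if f_exp[0] == 0 or f_exp[1] == 0:
        matches = ((observed_intra == round(f_exp[0]))
                   and (observed_inter == round(f_exp[1])))
        chi2, p = (0.0, 1.0) if matches else (math.inf, 0.0)
    else:
        chi2, p = stats.chisquare([observed_intra, observed_inter],
                                  f_exp=f_exp)
        chi2, p = float(chi2), float(p)
    return MCResult(n_events, observed_intra, observed_inter, expected_intra,
                    expected_inter, chi2, p, closed_form, n_runs, seed)


def nearest_element_distance(
    breakpoints: Sequence[Tuple[str, int]],
    annotation: RepeatAnnotation,
    element_class: Optional[str] = None,
) -> List[DistanceRecord]:
    """Distance from each breakpoint to the closest same-chromosome element.

    Distance is 0 when the breakpoint lies within an element; otherwise the
    base-pair gap to the nearest element boundary.  Chromosomes with no
    element of the class yield the ``no_element_on_chrom`` category.
    """
    records = list(annotation.of_class(element_class)
                   if element_class else annotation)
    by_chrom: Dict[str, list] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        rs.sort(key=lambda r: r.start)
    arrays = {c: (np.array([r.start for r in rs], dtype=np.int64),
                  np.array([r.end for r in rs], dtype=np.int64))
              for c, rs in by_chrom.items()}
    out = []
    for chrom, pos in breakpoints:
        if chrom not in arrays:
            out.append(DistanceRecord(chrom, pos, None, None, math.inf,
                                      NO_ELEMENT))
            continue
        starts, ends = arrays[chrom]
        rs = by_chrom[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        best, dist = None, math.inf
        if k >= 0:
            if pos < ends[k]:
                best, dist = rs[k], 0.0
            else:
                best, dist = rs[k], float(pos - (ends[k] - 1))
        if dist > 0 and k + 1 < len(rs):
            d_right = float(starts[k + 1] - pos)
            if d_right < dist:
                best, dist = rs[k + 1], d_right
        if dist == 0:
            cat = IN_ELEMENT
        elif dist < 1_000:
            cat = LT_1KB
        elif dist < 10_000:
            cat = KB_1_10
        elif dist < 100_000:
            cat = KB_10_100
        else:
            cat = GT_100KB
        out.append(DistanceRecord(chrom, pos, best.copy_id, best.element_class,
                                  dist, cat))
    return out


def distance_category_counts(records: Sequence[DistanceRecord]
                             ) -> Dict[str, int]:
    counts = {cat: 0 for cat in DISTANCE_CATEGORIES}
    for r in records:
        counts[r.category] += 1
    return counts


def linearize_breakpoints(
    junctions: Sequence[Junction],
    chrom_order: Sequence[str],
    chrom_lengths: Dict[str, int],
) -> List[Tuple[int, int]]:
    """Junctions as (x, y) points on the linearly concatenated genome.

    One point per junction; endpoint A is the lexicographically smaller
    (chromosome-order index, position).
    """
    order = {c: i for i, c in enumerate(chrom_order)}
    offsets = {}
    acc = 0
    for c in chrom_order:
        offsets[c] = acc
        acc += chrom_lengths[c]
    points = []
    for j in junctions:
        jc = j.canonical(order)
        points.append((offsets[jc.chromA] + jc.posA,
                       offsets[jc.chromB] + jc.posB))
    return points


def plot_breakpoints(points, chrom_order, chrom_lengths, path,
                     title: str = "breakpoint 2D plot"):
    """Scatter of linearized junctions with chromosome boundary guides."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if points:
        xs, ys = zip(*points)
        ax.scatter(xs, ys, s=6, alpha=0.6)
    acc = 0
    for c in chrom_order:
        acc += chrom_lengths[c]
        ax.axvline(acc, lw=0.4, color="grey")
        ax.axhline(acc, lw=0.4, color="grey")
    ax.set_xlim(0, acc)
    ax.set_ylim(0, acc)
    ax.set_xlabel("linearized genome position (end A)")
    ax.set_ylabel("linearized genome position (end B)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
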