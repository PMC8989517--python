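"""Self-contained validation experiments.

Each experiment builds its own synthetic inputs, runs one pipeline stage
against either an independent reference implementation (oracle) or the
simulator's ground truth, and returns a flat dict of measured quantities.
They are deliberately reusable: the test suite asserts on their outputs
and the acceptance script reports them.

Problem sizes are desk scale — 1 Mb genomes for exhaustive oracle
comparisons, a 10 Mb genome for the simulator and long-read scenes — so a
full run finishes in minutes on one CPU.
"""
from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .breakpoints import (
    mc_intra_inter,
    nearest_element_distance,
    permutation_enrichment,
)
from .cnv import RegionSet, cnv_difference, high_cnv_regions
from .guides import find_guide_matches
from .longread import (
    KmerIndex,
    call_translocations,
    evaluate_calls,
    filter_reads,
    find_element_reads,
    map_flanks,
)
from .pipeline import RunConfig, run_all
from .rearrange import (
    CopyNumberTruth,
    CutModel,
    Junction,
    RejoinModel,
    rejoin,
    select_cut_sites,
)
from .sequtils import revcomp, seq_to_array
from .synthetic import (
    ALU_LIKE,
    Genome,
    GenomeSpec,
    alu_like_spec,
    embed_repeats,
    generate_genome,
    simulate_binned_counts,
    simulate_long_reads,
)

SGALU = "TGTAATCCCAGCACTTTGGG"


def _sub_seed(seed: int, salt: int) -> int:
    return (1_000_003 * seed + 7919 * salt + 13) % (2**31)


# ---------------------------------------------------------------------------
# 1. guide search vs independent Hamming-scan oracle
# ---------------------------------------------------------------------------

def oracle_guide_matches(genome: Genome, guide: str, max_mismatch: int,
                         require_pam: bool = False):
    """Reference guide-site scan, independent of the production code path.

    Accumulates per-position mismatch counts with 20 shifted whole-array
    comparisons (the production scan uses chunked sliding windows); PAM
    checks are done by direct string indexing on the few candidates.
    """
    out = []
    for chrom, seq in genome.chromosomes.items():
        arr = seq_to_array(seq)
        n = len(arr)
        if n < 20:
            continue
        for strand, pattern_seq in (("+", guide), ("-", revcomp(guide))):
            pattern = seq_to_array(pattern_seq)
            mm = np.zeros(n - 19, dtype=np.int16)
            for j in range(20):
                mm += arr[j : n - 19 + j] != pattern[j]
            for pos in np.flatnonzero(mm <= max_mismatch):
                pos = int(pos)
                if require_pam:
                    if strand == "+":
                        if pos + 23 > n or seq[pos + 21] != "G" or seq[pos + 22] != "G":
                            continue
                    else:
                        if pos < 3 or seq[pos - 3] != "C" or seq[pos - 2] != "C":
                            continue
                window = seq[pos : pos + 20]
                matched = window if strand == "+" else revcomp(window)
                out.append((chrom, pos, strand, int(mm[pos]), matched))
    out.sort()
    return out


def guide_oracle_experiment(seed: int, n_genomes: int = 10,
                            genome_length: int = 1_000_000) -> Dict:
    """Exact agreement of the production guide scan with the oracle on
    random genomes carrying planted exact/1-mismatch/2-mismatch sites."""
    n_total = 0
    n_configs = 0
    n_agree = 0
    for g in range(n_genomes):
        s = _sub_seed(seed, g)
        genome0 = generate_genome(GenomeSpec(1, (genome_length,), 0.45, seed=s))
        genome, _ = embed_repeats(
            genome0,
            [alu_like_spec(copy_number=40, guide_exact_fraction=0.4,
                           mismatch_profile=(0.3, 0.2), divergence_rate=0.1)],
            SGALU, seed=s + 1)
        for k in (0, 1, 2):
            for pam in (False, True):
                got = sorted(
                    (m.chrom, m.protospacer_start, m.strand,
                     m.mismatch_count, m.matched_sequence)
                    for m in find_guide_matches(genome, SGALU, k,
                                                require_pam=pam))
                expected = oracle_guide_matches(genome, SGALU, k,
                                                require_pam=pam)
                n_configs += 1
                n_agree += int(got == expected)
                n_total += len(expected)
    return {
        "agreement_fraction": n_agree / n_configs,
        "n_configurations": n_configs,
        "n_matches_compared": n_total,
    }


# ---------------------------------------------------------------------------
# 2. simulator conservation
# ---------------------------------------------------------------------------

def _default_scene(seed: int, max_cuts: Optional[int] = None,
                   cut_probability: float = 1.0):
    """10 Mb genome with the default repeat census, cut at short-element
    guide sites."""
    config = RunConfig(seed=seed)
    genome0 = generate_genome(config.genome_spec())
    specs = config.repeat_specs()
    g1, ann1 = embed_repeats(genome0, [specs["sgL1"]], config.guides["sgL1"],
                             seed=_sub_seed(seed, 1))
    genome, ann2 = embed_repeats(g1, [specs["sgAlu"]], config.guides["sgAlu"],
                                 seed=_sub_seed(seed, 2),
                                 occupied=ann1.intervals())
    annotation = ann1.merged_with(ann2)
    matches = find_guide_matches(genome, config.guides["sgAlu"], 2)
    cuts = select_cut_sites(matches, CutModel(
        cut_probability=cut_probability, max_cuts=max_cuts,
        seed=_sub_seed(seed, 3)))
    return config, genome, annotation, cuts


def conservation_experiment(seed: int, n_cuts: int = 200) -> Dict:
    """Exact per-bin copy accounting and junction/cut consistency on a
    10 Mb genome with ~200 cuts (5% loss, 5% duplication)."""
    config, genome, _, cuts = _default_scene(seed, max_cuts=n_cuts)
    model = RejoinModel(seed=_sub_seed(seed, 4))
    derivative, junctions, truth = rejoin(genome, cuts, model,
                                          bin_size=config.bin_size)
    recomputed = CopyNumberTruth.from_coverage(derivative.coverage(),
                                               config.bin_size)
    bin_mismatches = sum(
        int((recomputed.base_sum[c] != truth.base_sum[c]).sum())
        for c in truth.base_sum)
    # every junction end must coincide with a cut +- resection
    violations = 0
    max_dev = 0
    for j in junctions:
        for chrom, pos in ((j.chromA, j.posA), (j.chromB, j.posB)):
            positions = cuts.get(chrom)
            if positions is None or len(positions) == 0:
                violations += 1
                continue
            dev = int(np.abs(positions - pos).min())
            max_dev = max(max_dev, dev)
            if dev > model.end_resection_max:
                violations += 1
    return {
        "n_cuts": int(sum(len(v) for v in cuts.values())),
        "n_junctions": len(junctions),
        "bin_accounting_mismatches": bin_mismatches,
        "junction_cut_violations": violations,
        "max_junction_cut_deviation": max_dev,
    }


# ---------------------------------------------------------------------------
# 3. CNV parameter recovery
# ---------------------------------------------------------------------------

def cnv_recovery_experiment(seed: int, n_seeds: int = 20,
                            depth: float = 100.0,
                            n_changed_bins: int = 10) -> Dict:
    """Sensitivity and FDR of high-CNV calling for |delta copy| >= 1
    at depth 100 per bin, averaged over independent simulations."""
    lengths = {f"chr{i+1}": 2_500_000 for i in range(4)}
    bin_size = 50_000
    sens, fdr = [], []
    for r in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 100 + r))
        truth = CopyNumberTruth.baseline(lengths, bin_size)
        copy = {c: np.ones(len(v), dtype=float)
                for c, v in truth.base_sum.items()}
        chroms = list(copy)
        all_bins = [(c, i) for c in chroms for i in range(len(copy[c]))]
        changed = rng.choice(len(all_bins), size=n_changed_bins, replace=False)
        true_bins = set()
        for rank, bi in enumerate(changed):
            c, i = all_bins[bi]
            copy[c][i] = 2.0 if rank % 2 == 0 else 0.0  # +1 gain / -1 loss
            true_bins.add((c, i))
        widths = truth.bin_widths()
        changed_truth = CopyNumberTruth(
            bin_size, dict(lengths),
            {c: (copy[c] * widths[c]).astype(np.int64) for c in copy})
        sample = simulate_binned_counts(changed_truth, depth,
                                        seed=_sub_seed(seed, 200 + r),
                                        sample_id="gcr")
        control = simulate_binned_counts(truth, depth,
                                         seed=_sub_seed(seed, 300 + r),
                                         sample_id="nc")
        profile = cnv_difference(sample, control)
        regions = high_cnv_regions(profile, "abs_quantile", q=0.95)
        called = set()
        for chrom, s, e in regions:
            for i in range(s // bin_size, -(-e // bin_size)):
                called.add((chrom, i))
        tp = len(called & true_bins)
        sens.append(tp / len(true_bins))
        fdr.append((len(called) - tp) / len(called) if called else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "n_simulations": n_seeds,
    }


# ---------------------------------------------------------------------------
# 4. permutation-test calibration and power
# ---------------------------------------------------------------------------

def _random_regions(lengths: Dict[str, int], fraction: float,
                    interval_size: int, rng: np.random.Generator) -> RegionSet:
    total = sum(lengths.values())
    n_intervals = int(total * fraction / interval_size)
    names = list(lengths)
    sizes = np.array([lengths[c] for c in names], dtype=float)
    w = (sizes - interval_size).clip(0)
    w /= w.sum()
    placed = []
    occupied = {c: [] for c in names}
    while len(placed) < n_intervals:
        ci = int(rng.choice(len(names), p=w))
        chrom = names[ci]
        start = int(rng.integers(0, lengths[chrom] - interval_size))
        end = start + interval_size
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        placed.append((chrom, start, end))
    return RegionSet(placed)


def _random_junctions(lengths: Dict[str, int], n: int,
                      rng: np.random.Generator,
                      regions: Optional[RegionSet] = None,
                      enrichment: float = 1.0) -> List[Junction]:
    """Junctions with endpoints uniform over the genome, optionally with a
    density ratio ``enrichment`` inside ``regions`` relative to outside."""
    names = list(lengths)
    sizes = np.array([lengths[c] for c in names], dtype=float)
    w = sizes / sizes.sum()
    region_list = list(regions) if regions is not None else []
    region_total = sum(e - s for _, s, e in region_list)
    genome_total = int(sizes.sum())
    p_in = (enrichment * region_total
            / (enrichment * region_total + (genome_total - region_total)))

    def draw_point():
        if regions is not None and rng.random() < p_in:
            k = int(rng.integers(0, len(region_list)))
            chrom, s, e = region_list[k]
            return chrom, int(rng.integers(s, e))
        chrom = names[int(rng.choice(len(names), p=w))]
        return chrom, int(rng.integers(0, lengths[chrom]))

    out = []
    for _ in range(n):
        ca, pa = draw_point()
        cb, pb = draw_point()
        cls = "translocation_inter" if ca != cb else "translocation_intra"
        out.append(Junction(ca, pa, "+", cb, pb, "-", cls))
    return out


def permutation_calibration_experiment(
    seed: int,
    n_replicates: int = 500,
    n_power_replicates: int = 200,
    n_junctions: int = 100,
    n_perm: int = 1000,
    region_fraction: float = 0.10,
) -> Dict:
    """Type-I error of the enrichment test with independent breakpoints
    (regions = 10% of the genome) and power with 2x-enriched breakpoints."""
    lengths = {f"chr{i+1}": 2_500_000 for i in range(4)}
    rng = np.random.default_rng(_sub_seed(seed, 0))
    regions = _random_regions(lengths, region_fraction, 50_000, rng)
    rejections = 0
    for r in range(n_replicates):
        junctions = _random_junctions(lengths, n_junctions, rng)
        res = permutation_enrichment(junctions, regions, lengths,
                                     n_perm=n_perm,
                                     seed=_sub_seed(seed, 1000 + r))
        rejections += int(res.p_value < 0.05)
    power_hits = 0
    for r in range(n_power_replicates):
        junctions = _random_junctions(lengths, n_junctions, rng,
                                      regions=regions, enrichment=2.0)
        res = permutation_enrichment(junctions, regions, lengths,
                                     n_perm=n_perm,
                                     seed=_sub_seed(seed, 50_000 + r))
        power_hits += int(res.p_value < 0.05)
    return {
        "type_i_error_rate": rejections / n_replicates,
        "power_2x_enrichment": power_hits / n_power_replicates,
        "n_replicates": n_replicates,
        "n_power_replicates": n_power_replicates,
    }


# ---------------------------------------------------------------------------
# 5. Monte-Carlo closed-form agreement
# ---------------------------------------------------------------------------

#: chromosome lengths in Mb resembling the human haploid assembly
#: (chr1..chr22, chrX)
HUMAN_LIKE_LENGTHS_MB = (248, 242, 198, 190, 182, 171, 159, 145, 138, 134,
                         135, 133, 114, 107, 102, 90, 83, 80, 59, 64, 47,
                         51, 156)


def mc_closed_form_experiment(seed: int, n_pairs: int = 100_000) -> Dict:
    """Simulated intra-chromosomal fraction vs the closed form
    sum (L_i/L)^2, over several chromosome-length vectors."""
    vectors = {
        "single": [100],
        "two_equal": [100, 100],
        "human_like": list(HUMAN_LIKE_LENGTHS_MB),
        "skewed": [500, 100, 50, 10, 5],
        "uniform_8": [60] * 8,
    }
    max_z = 0.0
    results = {}
    dummy = [Junction("c1", 1, "+", "c1", 2, "-", "translocation_intra")]
    for i, (name, mb) in enumerate(vectors.items()):
        lengths = {f"c{j+1}": m * 1_000_000 for j, m in enumerate(mb)}
        res = mc_intra_inter(dummy, lengths, n_runs=1,
                             seed=_sub_seed(seed, i), n_events=n_pairs)
        sim = res.expected_intra_mean / n_pairs
        cf = res.closed_form_intra_fraction
        se = float(np.sqrt(cf * (1 - cf) / n_pairs))
        z = abs(sim - cf) / se if se > 0 else 0.0
        results[name] = (sim, cf, z)
        max_z = max(max_z, z)
    return {
        "max_abs_z": max_z,
        "n_length_vectors": len(vectors),
        "single_chrom_fraction": results["single"][0],
        "two_equal_closed_form": results["two_equal"][1],
    }


# ---------------------------------------------------------------------------
# 6. nearest-element oracle equivalence
# ---------------------------------------------------------------------------

def oracle_nearest_distance(breakpoints, records):
    """Brute-force exhaustive scan over all same-chromosome elements."""
    out = []
    for chrom, pos in breakpoints:
        best = np.inf
        for r in records:
            if r.chrom != chrom:
                continue
            if r.start <= pos < r.end:
                d = 0.0
            elif pos < r.start:
                d = float(r.start - pos)
            else:
                d = float(pos - (r.end - 1))
            best = min(best, d)
        out.append(best)
    return out


def nearest_oracle_experiment(seed: int, n_breakpoints: int = 1000,
                              n_elements: int = 1000) -> Dict:
    """Production nearest-element distances vs exhaustive scan."""
    from .synthetic import RepeatAnnotation, RepeatRecord

    rng = np.random.default_rng(_sub_seed(seed, 0))
    lengths = {f"chr{i+1}": 2_500_000 for i in range(4)}
    names = list(lengths)
    records = []
    occupied = {c: [] for c in names}
    i = 0
    while i < n_elements:
        chrom = names[int(rng.integers(0, len(names)))]
        size = int(rng.integers(100, 2000))
        start = int(rng.integers(0, lengths[chrom] - size))
        end = start + size
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        records.append(RepeatRecord(chrom, start, end, ALU_LIKE, "+",
                                    f"el_{i}", 0))
        i += 1
    records.sort(key=lambda r: (r.chrom, r.start))
    annotation = RepeatAnnotation(records)
    breakpoints = [(names[int(rng.integers(0, len(names)))],
                    int(rng.integers(0, 2_500_000)))
                   for _ in range(n_breakpoints)]
    got = [r.distance for r in
           nearest_element_distance(breakpoints, annotation, ALU_LIKE)]
    expected = oracle_nearest_distance(breakpoints, records)
    mismatches = sum(1 for a, b in zip(got, expected) if a != b)
    return {
        "n_breakpoints": n_breakpoints,
        "distance_mismatches": mismatches,
    }


# ---------------------------------------------------------------------------
# 7. long-read caller on the default scene
# ---------------------------------------------------------------------------

def _run_longread_arm(genome, annotation, derivative, truth_inter,
                      error_rate, coverage, seed):
    n_reads = int(coverage * derivative.total_length / 8000)
    reads = simulate_long_reads(derivative, n_reads, (8000, 500), error_rate,
                                seed=seed)
    reads = filter_reads(reads, min_length=500)
    consensi = {ALU_LIKE: annotation.consensi[ALU_LIKE]}
    hits = find_element_reads(reads, consensi)
    index = KmerIndex(genome)
    by_id = {r.read_id: r for r in reads}
    alignments = []
    for hit in hits:
        alignments.extend(map_flanks(by_id[hit.read_id], hit, genome,
                                     index=index))
    calls = call_translocations(hits, alignments)
    inter_calls = [c for c in calls
                   if c.junction.junction_class == "translocation_inter"]
    precision, recall, _ = evaluate_calls(inter_calls, truth_inter,
                                          tolerance=500)
    return precision, recall, len(inter_calls)


def longread_experiment(seed: int, coverage: float = 15.0,
                        n_junction_target: int = 30) -> Dict:
    """Caller performance on the default 10 Mb scene with ~30 junctions:
    error-free reads, then 5% uniform error, at 15x long-read depth."""
    config, genome, annotation, cuts = _default_scene(
        seed, max_cuts=n_junction_target)
    derivative, junctions, _ = rejoin(genome, cuts,
                                      RejoinModel(seed=_sub_seed(seed, 4)),
                                      bin_size=config.bin_size)
    truth_inter = [j for j in junctions if j.is_inter]
    p0, r0, n0 = _run_longread_arm(genome, annotation, derivative,
                                   truth_inter, 0.0, coverage,
                                   _sub_seed(seed, 5))
    p5, r5, n5 = _run_longread_arm(genome, annotation, derivative,
                                   truth_inter, 0.05, coverage,
                                   _sub_seed(seed, 6))
    return {
        "n_junctions": len(junctions),
        "n_truth_inter": len(truth_inter),
        "precision_error_free": p0,
        "recall_error_free": r0,
        "precision_5pct_error": p5,
        "recall_5pct_error": r5,
    }


# ---------------------------------------------------------------------------
# 8. negative control
# ---------------------------------------------------------------------------

def negative_control_experiment(seed: int) -> Dict:
    """The no-match guide arm of the full pipeline must be quiet: zero
    cuts, zero junctions, CNV profile mean indistinguishable from zero."""
    config = RunConfig(seed=seed)
    report = run_all(config, out_dir=None, write_outputs=False)
    nc = report["arms"]["sgNC"]
    n_bins = 4 * (2_500_000 // config.bin_size)
    # per-bin difference of two Poisson(depth) counts has sd sqrt(2*depth)
    sem = float(np.sqrt(2 * config.depth_per_bin) / np.sqrt(n_bins))
    return {
        "nc_matches": nc["n_matches"],
        "nc_cuts": nc["n_cuts"],
        "nc_junctions": nc["n_junctions"],
        "nc_cnv_profile_mean": nc["cnv_profile_mean"],
        "nc_cnv_mean_sem": sem,
        "nc_permutation_degenerate": bool(
            nc["stats"].get("permutation", {}).get("degenerate", True)),
    }
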