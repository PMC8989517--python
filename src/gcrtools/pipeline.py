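"""End-to-end pipeline: simulate a GCR experiment and analyse it.

One :func:`run_all` call reproduces the full in-silico experiment on a
synthetic genome: embed repeats carrying the guide sequences, enumerate
guide matching sites, cut and rejoin per guide arm (including the
negative-control guide, which matches nowhere and must leave the genome
untouched), simulate short-read bin counts for every arm plus the control,
compute CNV profiles and high-CNV regions, run the breakpoint statistics,
simulate long reads over the rearranged genome and call translocations,
and evaluate everything against the simulator's ground truth.

Every stochastic stage has its own seed derived from the config's base
seed, so stages can be re-run without global drift and the whole report is
byte-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .breakpoints import (
    distance_category_counts,
    linearize_breakpoints,
    mc_intra_inter,
    nearest_element_distance,
    breakpoint_list,
    permutation_enrichment,
)
from .cnv import cnv_correlation, cnv_difference, common_regions, high_cnv_regions
from .errors import GcrToolsError
from .guides import find_guide_matches
from .longread import (
    KmerIndex,
    call_translocations,
    evaluate_calls,
    filter_reads,
    find_element_reads,
    map_flanks,
)
from .rearrange import (
    CopyNumberTruth,
    CutModel,
    RejoinModel,
    rejoin,
    select_cut_sites,
)
from .synthetic import (
    ALU_LIKE,
    L1_LIKE,
    GenomeSpec,
    RepeatSpec,
    embed_repeats,
    generate_genome,
    simulate_binned_counts,
    simulate_long_reads,
)

# guide set: one targeting the long-element family, one the short-element
# family, and a negative control with no genomic match
SGL1 = "TTCCAATCAATAGAAAAAGA"
SGALU = "TGTAATCCCAGCACTTTGGG"
SGNC = "CGCTTCCGCGGCCCGTTCAA"

_STAGES = ("genome", "repeats", "cuts", "rejoin", "counts", "reads", "stats")


def derive_stage_seeds(base_seed: int) -> Dict[str, int]:
    """Deterministic, independent per-stage seeds below 2^31."""
    return {stage: (1_000_003 * base_seed + 7919 * i + 1) % (2**31)
            for i, stage in enumerate(_STAGES)}


@dataclass
class RunConfig:
    """Complete, serialisable configuration of a pipeline run."""

    # genome
    n_chromosomes: int = 4
    chrom_length: int = 2_500_000
    gc_fraction: float = 0.41
    # repeat census (desk-scale: ~5% of the genome repetitive, short-element
    # guide sites roughly 8x more numerous than long-element sites)
    l1_copies: int = 60
    l1_consensus_length: int = 6000
    l1_guide_fractions: Tuple[float, float, float] = (0.25, 0.20, 0.15)
    l1_divergence: float = 0.05
    alu_copies: int = 400
    alu_consensus_length: int = 300
    alu_guide_fractions: Tuple[float, float, float] = (0.30, 0.20, 0.10)
    alu_divergence: float = 0.10
    # guides
    guides: Dict[str, str] = field(default_factory=lambda: {
        "sgL1": SGL1, "sgAlu": SGALU, "sgNC": SGNC})
    max_mismatch: int = 2
    # cut / rejoin models
    cut_probability: float = 0.25
    cut_offset: int = 17
    max_cuts: Optional[int] = None
    intra_bias: float = 0.7
    distance_scale: float = 500_000.0
    segment_loss_probability: float = 0.05
    segment_duplication_probability: float = 0.05
    end_resection_max: int = 10
    # binned counts / CNV
    bin_size: int = 50_000
    depth_per_bin: float = 100.0
    cnv_normalization: str = "total_count"
    cnv_quantile: float = 0.95
    # statistics
    n_permutations: int = 1000
    mc_runs: int = 10
    # long reads
    longread_arms: Tuple[str, ...] = ("sgAlu",)
    longread_coverage: float = 5.0
    longread_mean_length: int = 8000
    longread_min_length: int = 500
    longread_error_rate: float = 0.05
    longread_min_flank: int = 200
    longread_min_identity: float = 0.8
    # seeds
    seed: int = 0
    stage_seeds: Optional[Dict[str, int]] = None

    def __post_init__(self):
        if self.stage_seeds is None:
            self.stage_seeds = derive_stage_seeds(self.seed)
        missing = set(_STAGES) - set(self.stage_seeds)
        if missing:
            raise GcrToolsError(f"missing stage seeds: {sorted(missing)}")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["l1_guide_fractions"] = list(self.l1_guide_fractions)
        data["alu_guide_fractions"] = list(self.alu_guide_fractions)
        data["longread_arms"] = list(self.longread_arms)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("l1_guide_fractions", "alu_guide_fractions",
                    "longread_arms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    # -- derived objects ---------------------------------------------------
    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(
            n_chromosomes=self.n_chromosomes,
            chrom_lengths=(self.chrom_length,) * self.n_chromosomes,
            gc_fraction=self.gc_fraction,
            seed=self.stage_seeds["genome"],
        )

    def repeat_specs(self) -> Dict[str, RepeatSpec]:
        e1, m1, m2 = self.l1_guide_fractions
        a1, am1, am2 = self.alu_guide_fractions
        return {
            "sgL1": RepeatSpec(L1_LIKE, self.l1_consensus_length,
                               self.l1_copies, e1, (m1, m2),
                               self.l1_divergence),
            "sgAlu": RepeatSpec(ALU_LIKE, self.alu_consensus_length,
                                self.alu_copies, a1, (am1, am2),
                                self.alu_divergence),
        }


GUIDE_TO_CLASS = {"sgL1": L1_LIKE, "sgAlu": ALU_LIKE}


class _Logger:
    def __init__(self, path: Optional[Path]):
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text("")

    def log(self, stage: str, **fields):
        if self.path is None:
            return
        entry = {"stage": stage, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def run_all(config: RunConfig, out_dir: Optional[str] = None,
            write_outputs: bool = True) -> dict:
    """Execute the full pipeline and return (and optionally write) the
    structured run report."""
    out = Path(out_dir) if out_dir else None
    if out is not None and write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    logger = _Logger(out / "run_log.jsonl" if out is not None else None)
    seeds = config.stage_seeds
    report: dict = {
        "tool_version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "arms": {},
    }

    def _stage(name, fn, **params):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            digest = json.dumps(params, sort_keys=True, default=str)
            raise GcrToolsError(
                f"pipeline stage {name!r} failed on inputs {digest}: {exc}"
            ) from exc
        logger.log(name, seed=seeds.get(name.split(":")[0]),
                   params=params, wall_time_s=round(time.perf_counter() - t0, 3))
        return result

    # --- genome and repeats ------------------------------------------------
    genome0 = _stage("genome", lambda: generate_genome(config.genome_spec()))
    specs = config.repeat_specs()

    def _embed():
        g1, ann_l1 = embed_repeats(genome0, [specs["sgL1"]],
                                   config.guides["sgL1"],
                                   seed=seeds["repeats"])
        g2, ann_alu = embed_repeats(g1, [specs["sgAlu"]],
                                    config.guides["sgAlu"],
                                    seed=seeds["repeats"] + 1,
                                    occupied=ann_l1.intervals())
        return g2, ann_l1.merged_with(ann_alu)

    genome, annotation = _stage("repeats", _embed)

    # --- guide search ------------------------------------------------------
    matches = {}
    for gname, gseq in config.guides.items():
        matches[gname] = _stage(
            f"cuts:search_{gname}",
            lambda gs=gseq: find_guide_matches(genome, gs,
                                               max_mismatch=config.max_mismatch),
            guide=gname)

    # --- per-arm simulation and analysis ------------------------------------
    control_truth = CopyNumberTruth.baseline(genome.lengths, config.bin_size)
    counts_nc = _stage("counts:control", lambda: simulate_binned_counts(
        control_truth, config.depth_per_bin, seed=seeds["counts"],
        sample_id="control"))

    arm_data = {}
    for i, gname in enumerate(config.guides):
        cut_model = CutModel(config.cut_probability, config.cut_offset,
                             config.max_cuts, seed=seeds["cuts"] + i)
        cuts = select_cut_sites(matches[gname], cut_model)
        rejoin_model = RejoinModel(
            config.intra_bias, config.distance_scale,
            config.segment_loss_probability,
            config.segment_duplication_probability,
            config.end_resection_max, seed=seeds["rejoin"] + i)
        derivative, junctions, truth = _stage(
            f"rejoin:{gname}",
            lambda c=cuts, m=rejoin_model: rejoin(genome, c, m,
                                                  bin_size=config.bin_size),
            guide=gname)
        counts = simulate_binned_counts(truth, config.depth_per_bin,
                                        seed=seeds["counts"] + 1 + i,
                                        sample_id=gname)
        profile = cnv_difference(counts, counts_nc,
                                 normalization=config.cnv_normalization)
        regions = high_cnv_regions(profile, "abs_quantile",
                                   q=config.cnv_quantile)
        n_cuts = int(sum(len(v) for v in cuts.values()))
        arm_data[gname] = dict(cuts=cuts, derivative=derivative,
                               junctions=junctions, truth=truth,
                               profile=profile, regions=regions)
        arm_report = {
            "n_matches": len(matches[gname]),
            "n_cuts": n_cuts,
            "n_junctions": len(junctions),
            "junction_classes": _class_counts(junctions),
            "cnv_profile_mean": float(np.mean(profile.flat())),
            "cnv_profile_sd": float(np.std(profile.flat())),
            "n_high_cnv_regions": len(regions),
        }
        report["arms"][gname] = arm_report

    # --- common high-CNV regions and breakpoint statistics -------------------
    gcr_arms = [g for g in config.guides if g in GUIDE_TO_CLASS]
    if len(gcr_arms) >= 2:
        common = common_regions(arm_data[gcr_arms[0]]["regions"],
                                arm_data[gcr_arms[1]]["regions"])
        p1 = arm_data[gcr_arms[0]]["profile"]
        p2 = arm_data[gcr_arms[1]]["profile"]
        report["cnv_correlation"] = {
            "per_bin": dataclasses.asdict(cnv_correlation(p1, p2, "per_bin")),
            "per_chromosome": dataclasses.asdict(
                cnv_correlation(p1, p2, "per_chromosome")),
        }
        report["common_high_cnv_bp"] = common.total_length
    else:
        common = None

    for gname in config.guides:
        junctions = arm_data[gname]["junctions"]
        stats_report = {}
        if common is not None:
            perm = permutation_enrichment(
                junctions, common, genome.lengths,
                n_perm=config.n_permutations, seed=seeds["stats"])
            stats_report["permutation"] = dataclasses.asdict(perm)
        if junctions:
            mc = mc_intra_inter(junctions, genome.lengths,
                                n_runs=config.mc_runs, seed=seeds["stats"] + 1)
            stats_report["mc_intra_inter"] = dataclasses.asdict(mc)
            cls = GUIDE_TO_CLASS.get(gname)
            if cls:
                dist = nearest_element_distance(
                    breakpoint_list(junctions), annotation, cls)
                stats_report["nearest_element"] = distance_category_counts(dist)
            stats_report["linearized_points"] = len(
                linearize_breakpoints(junctions, genome.names, genome.lengths))
        report["arms"][gname]["stats"] = stats_report

    # --- long reads ----------------------------------------------------------
    index = None
    for gname in config.longread_arms:
        if gname not in arm_data:
            continue
        derivative = arm_data[gname]["derivative"]
        truth_junctions = [j for j in arm_data[gname]["junctions"] if j.is_inter]
        n_reads = int(config.longread_coverage * derivative.total_length
                      / config.longread_mean_length)
        reads = _stage(
            f"reads:{gname}",
            lambda d=derivative, n=n_reads: simulate_long_reads(
                d, n, (config.longread_mean_length, config.longread_min_length),
                config.longread_error_rate, seed=seeds["reads"]),
            n_reads=n_reads, guide=gname)
        reads = filter_reads(reads, min_length=config.longread_min_length)
        cls = GUIDE_TO_CLASS.get(gname)
        consensi = {cls: annotation.consensi[cls]} if cls else {}
        hits = find_element_reads(reads, consensi,
                                  min_identity=config.longread_min_identity)
        if index is None:
            index = KmerIndex(genome)
        alignments = []
        by_id = {r.read_id: r for r in reads}
        for hit in hits:
            alignments.extend(map_flanks(by_id[hit.read_id], hit, genome,
                                         index=index,
                                         min_flank=config.longread_min_flank))
        calls = call_translocations(hits, alignments,
                                    min_flank=config.longread_min_flank)
        inter_calls = [c for c in calls
                       if c.junction.junction_class == "translocation_inter"]
        precision, recall, table = evaluate_calls(inter_calls, truth_junctions)
        report["arms"][gname]["longread"] = {
            "n_reads": len(reads),
            "n_element_reads": len(hits),
            "n_calls": len(calls),
            "n_inter_calls": len(inter_calls),
            "n_truth_inter": len(truth_junctions),
            "precision_inter": precision,
            "recall_inter": recall,
        }

    # --- outputs -------------------------------------------------------------
    if out is not None and write_outputs:
        from . import formats

        formats.write_fasta(genome, out / "genome.fasta")
        formats.write_repeat_bed(annotation, out / "repeats.bed")
        for gname in config.guides:
            arm_out = out / gname
            arm_out.mkdir(exist_ok=True)
            formats.junctions_to_bedpe(arm_data[gname]["junctions"],
                                       arm_out / "junctions.bedpe")
            formats.write_segment_map(arm_data[gname]["derivative"],
                                      arm_out / "segments.tsv")
            formats.write_cnv_profile(arm_data[gname]["profile"],
                                      arm_out / "cnv_profile.tsv")
            formats.write_regions_bed(arm_data[gname]["regions"],
                                      arm_out / "high_cnv_regions.bed")
            formats.write_copy_truth(arm_data[gname]["truth"],
                                     arm_out / "copy_truth.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _class_counts(junctions) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for j in junctions:
        counts[j.junction_class] = counts.get(j.junction_class, 0) + 1
    return dict(sorted(counts.items()))


def validate_report(report: dict) -> List[str]:
    """Structural check of a run report; returns a list of problems."""
    problems = []
    for key in ("tool_version", "config", "arms"):
        if key not in report:
            problems.append(f"missing top-level key {key!r}")
    for arm, data in report.get("arms", {}).items():
        for key in ("n_matches", "n_cuts", "n_junctions", "stats"):
            if key not in data:
                problems.append(f"arm {arm!r} missing {key!r}")
    return problems
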