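"""Readers and writers for the standard interchange formats.

FASTA goes through Biopython; tabular formats (BED, BEDPE, TSV) through
pandas.  All writers emit a provenance comment header; all readers skip
``#`` comment lines, so every file round-trips through its own reader.
"""
from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .cnv import CNVProfile, RegionSet
from .rearrange import CopyNumberTruth, DerivativeGenome, Junction
from .synthetic import BinnedCounts, Genome, LongRead, RepeatAnnotation, RepeatRecord

_PROVENANCE = f"# gcrtools {__version__}"


def _write_table(df: pd.DataFrame, path, what: str, header: bool = True):
    with open(path, "w") as fh:
        fh.write(f"{_PROVENANCE} {what}\n")
        df.to_csv(fh, sep="\t", index=False, header=header)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Genome, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.chromosomes.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> Genome:
    return Genome({rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(path, "fasta")})


def write_reads_fasta(reads: Sequence[LongRead], path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="")
               for r in reads]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# repeat annotation (BED6; score column = guide mismatch count)
# ---------------------------------------------------------------------------

def write_repeat_bed(annotation: RepeatAnnotation, path) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.copy_id, r.guide_mismatches, r.strand,
          r.element_class) for r in annotation],
        columns=["chrom", "start", "end", "name", "score", "strand", "class"],
    )
    _write_table(df, path, "repeat annotation (BED6 + class)", header=False)


def read_repeat_bed(path) -> RepeatAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "copy_id", "score",
                            "strand", "element_class"])
    records = [RepeatRecord(row.chrom, int(row.start), int(row.end),
                            row.element_class, row.strand, row.copy_id,
                            int(row.score))
               for row in df.itertuples()]
    return RepeatAnnotation(records)


# ---------------------------------------------------------------------------
# junctions (BEDPE: standard columns 1-6, name=class, score=support,
# strands in columns 9-10)
# ---------------------------------------------------------------------------

_BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                  "name", "score", "strand1", "strand2"]


def junctions_to_bedpe(junctions: Sequence[Junction], path) -> None:
    df = pd.DataFrame(
        [(j.chromA, j.posA, j.posA + 1, j.chromB, j.posB, j.posB + 1,
          j.junction_class, j.support, j.strandA, j.strandB)
         for j in junctions],
        columns=_BEDPE_COLUMNS,
    )
    _write_table(df, path, "junctions (BEDPE)")


def read_bedpe(path) -> List[Junction]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != _BEDPE_COLUMNS:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=_BEDPE_COLUMNS)
    return [Junction(r.chrom1, int(r.start1), r.strand1,
                     r.chrom2, int(r.start2), r.strand2,
                     r.name, int(r.score))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# region sets (BED3)
# ---------------------------------------------------------------------------

def write_regions_bed(regions: RegionSet, path) -> None:
    df = pd.DataFrame(list(regions), columns=["chrom", "start", "end"])
    _write_table(df, path, "regions (BED3)", header=False)


def read_regions_bed(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end"])
    return RegionSet([(r.chrom, int(r.start), int(r.end))
                      for r in df.itertuples()])


# ---------------------------------------------------------------------------
# binned counts / CNV profiles / copy truth (TSV)
# ---------------------------------------------------------------------------

def _grid_frame(bin_size: int, chrom_lengths: Dict[str, int],
                per_chrom: Dict[str, np.ndarray], value_name: str
                ) -> pd.DataFrame:
    rows = []
    for chrom, values in per_chrom.items():
        length = chrom_lengths[chrom]
        for i, v in enumerate(values):
            rows.append((chrom, i * bin_size, min((i + 1) * bin_size, length), v))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end",
                                       value_name])


def _frame_grid(df: pd.DataFrame, value_name: str, dtype):
    chrom_lengths: Dict[str, int] = {}
    per_chrom: Dict[str, list] = {}
    bin_size = int((df.bin_end - df.bin_start).max())
    for r in df.itertuples():
        per_chrom.setdefault(r.chrom, []).append(getattr(r, value_name))
        chrom_lengths[r.chrom] = int(r.bin_end)
    return bin_size, chrom_lengths, {c: np.array(v, dtype=dtype)
                                     for c, v in per_chrom.items()}


def write_binned_counts(counts: BinnedCounts, path) -> None:
    df = _grid_frame(counts.bin_size, counts.chrom_lengths, counts.counts,
                     "count")
    _write_table(df, path, f"binned counts sample={counts.sample_id}")


def read_binned_counts(path, sample_id: str = "sample") -> BinnedCounts:
    df = pd.read_csv(path, sep="\t", comment="#")
    bin_size, chrom_lengths, counts = _frame_grid(df, "count", np.int64)
    return BinnedCounts(sample_id=sample_id, bin_size=bin_size,
                        counts=counts, chrom_lengths=chrom_lengths)


def write_cnv_profile(profile: CNVProfile, path) -> None:
    df = _grid_frame(profile.bin_size, profile.chrom_lengths, profile.values,
                     "value")
    _write_table(df, path, f"CNV profile {profile.sample_pair}")


def read_cnv_profile(path, sample_pair: str = "sample-vs-control") -> CNVProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    bin_size, chrom_lengths, values = _frame_grid(df, "value", float)
    return CNVProfile(sample_pair=sample_pair, bin_size=bin_size,
                      values=values, chrom_lengths=chrom_lengths)


def write_copy_truth(truth: CopyNumberTruth, path) -> None:
    mean = truth.mean_copy()
    df = _grid_frame(truth.bin_size, truth.chrom_lengths, mean, "copy_number")
    _write_table(df, path, "per-bin copy-number truth")


# ---------------------------------------------------------------------------
# derivative segment map and long-read truth (TSV)
# ---------------------------------------------------------------------------

def write_segment_map(derivative: DerivativeGenome, path) -> None:
    rows = []
    for name, segs in derivative.segments.items():
        for order, (chrom, s, e, strand) in enumerate(segs):
            rows.append((name, order, chrom, s, e, strand))
    df = pd.DataFrame(rows, columns=["derivative_chrom", "order",
                                     "source_chrom", "start", "end", "strand"])
    _write_table(df, path, "derivative segment map")


def read_segment_map(path, source: Genome) -> DerivativeGenome:
    df = pd.read_csv(path, sep="\t", comment="#")
    segments: Dict[str, List[Tuple[str, int, int, str]]] = {}
    for r in df.sort_values(["derivative_chrom", "order"]).itertuples():
        segments.setdefault(r.derivative_chrom, []).append(
            (r.source_chrom, int(r.start), int(r.end), r.strand))
    return DerivativeGenome(source=source, segments=segments)


def write_read_truth(reads: Sequence[LongRead], path) -> None:
    rows = []
    for r in reads:
        for part, (chrom, s, e, strand) in enumerate(r.true_origin):
            rows.append((r.read_id, part, chrom, s, e, strand))
    df = pd.DataFrame(rows, columns=["read_id", "part_index", "chrom",
                                     "start", "end", "strand"])
    _write_table(df, path, "long-read origin truth")
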