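"""Synthetic genome, repeat and read simulation.

This module builds the fully-known ground truth that every analysis stage
of the toolkit is tested against: a random multi-chromosome genome, embedded
retrotransposon-like repeat copies (long ~6 kb L1-like elements and short
~300 bp Alu-like elements) carrying exact or mismatched copies of a CRISPR
guide, per-bin short-read counts drawn from a Poisson read-depth model, and
long reads sampled from a (possibly rearranged) genome with configurable
error rate and exact provenance bookkeeping.

All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CapacityError, DataError, SpecificationError
from .sequtils import (
    _ASCII_TO_BITS,
    BASES,
    array_to_seq,
    gc_content,
    mutate_guide,
    random_bases,
    revcomp,
    revcomp_array,
    seq_to_array,
)

L1_LIKE = "L1_like"
ALU_LIKE = "Alu_like"

#: offset of the embedded guide within each repeat consensus, as a fraction
#: of the consensus length.  Fixed so cut positions are computable from the
#: annotation alone.
GUIDE_OFFSET_FRACTION = 1 / 3


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a random synthetic genome."""

    n_chromosomes: int = 4
    chrom_lengths: Tuple[int, ...] = (2_500_000,) * 4
    gc_fraction: float = 0.41
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise SpecificationError("need at least one chromosome")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise SpecificationError("chrom_lengths must match n_chromosomes")
        if any(length < 10_000 for length in self.chrom_lengths):
            raise SpecificationError("every chromosome must be >= 10 kb")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SpecificationError("gc_fraction must lie in [0, 1]")


@dataclass
class Genome:
    """Named chromosome sequences; the coordinate frame for everything else."""

    chromosomes: Dict[str, str]

    @property
    def names(self) -> List[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self.chromosomes.values())

    def gc_fraction(self) -> float:
        gc = sum(gc_content(s) * len(s) for s in self.chromosomes.values())
        return gc / self.total_length


def generate_genome(spec: GenomeSpec) -> Genome:
    """Draw an i.i.d. random genome with the spec's GC content."""
    rng = np.random.default_rng(spec.seed)
    chroms = {}
    for i, length in enumerate(spec.chrom_lengths, start=1):
        chroms[f"chr{i}"] = array_to_seq(random_bases(length, spec.gc_fraction, rng))
    return Genome(chroms)


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatSpec:
    """A family of repeat copies to embed.

    ``guide_exact_fraction`` of the copies carry the exact 20-mer guide at a
    fixed offset; ``mismatch_profile`` gives the fractions carrying 1- and
    2-mismatch variants.  Remaining copies get a heavily mutated (5-mismatch)
    guide region so they are never counted as cut sites.  ``divergence_rate``
    is the per-base substitution probability applied to non-guide positions
    of each copy, emulating sequence divergence between element copies.
    """

    element_class: str
    consensus_length: int
    copy_number: int
    guide_exact_fraction: float = 0.0
    mismatch_profile: Tuple[float, float] = (0.0, 0.0)
    divergence_rate: float = 0.05

    def __post_init__(self):
        if self.copy_number < 0:
            raise SpecificationError("copy_number must be >= 0")
        fractions = (self.guide_exact_fraction, *self.mismatch_profile)
        if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
            raise SpecificationError("guide fractions must be >= 0 and sum <= 1")
        if self.consensus_length < 40:
            raise SpecificationError("consensus too short to hold a 20-mer guide")


def l1_like_spec(**kw) -> RepeatSpec:
    return RepeatSpec(L1_LIKE, kw.pop("consensus_length", 6000), **kw)


def alu_like_spec(**kw) -> RepeatSpec:
    return RepeatSpec(ALU_LIKE, kw.pop("consensus_length", 300), **kw)


@dataclass(frozen=True)
class RepeatRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    element_class: str
    strand: str
    copy_id: str
    guide_mismatches: int  # 0/1/2 for carriers, -1 for non-carriers


@dataclass
class RepeatAnnotation:
    """RepeatMasker-style interval annotation of embedded repeat copies.

    ``consensi`` keeps the consensus sequence each family's copies were
    derived from, so downstream element detection can align against it.
    """

    records: List[RepeatRecord] = field(default_factory=list)
    consensi: Dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def of_class(self, element_class: str) -> "RepeatAnnotation":
        return RepeatAnnotation(
            [r for r in self.records if r.element_class == element_class],
            {k: v for k, v in self.consensi.items() if k == element_class},
        )

    def merged_with(self, other: "RepeatAnnotation") -> "RepeatAnnotation":
        records = sorted(self.records + other.records,
                         key=lambda r: (r.chrom, r.start))
        return RepeatAnnotation(records, {**self.consensi, **other.consensi})

    def intervals(self) -> List[Tuple[str, int, int]]:
        return [(r.chrom, r.start, r.end) for r in self.records]


def guide_offset(consensus_length: int) -> int:
    """Offset of the guide within a consensus (fixed fraction of its length)."""
    return int(consensus_length * GUIDE_OFFSET_FRACTION)


def _variant_counts(spec: RepeatSpec) -> Tuple[int, int, int]:
    n = spec.copy_number
    n_exact = int(round(spec.guide_exact_fraction * n))
    n_mm1 = int(round(spec.mismatch_profile[0] * n))
    n_mm2 = int(round(spec.mismatch_profile[1] * n))
    if n_exact + n_mm1 + n_mm2 > n:
        n_mm2 = n - n_exact - n_mm1
    return n_exact, n_mm1, n_mm2


def embed_repeats(
    genome: Genome,
    repeat_specs: Sequence[RepeatSpec],
    guide: str,
    seed: int = 0,
    occupied: Optional[Iterable[Tuple[str, int, int]]] = None,
    max_attempts_per_copy: int = 200,
) -> Tuple[Genome, RepeatAnnotation]:
    """Write repeat copies into a genome at non-overlapping random positions.

    Returns a new genome (the input is not modified) plus the annotation of
    every placed copy.  ``occupied`` intervals (e.g. from a previous call
    for another repeat family) are avoided as well.
    """
    if len(guide) != 20:
        raise SpecificationError("guide must be a 20-mer")
    rng = np.random.default_rng(seed)
    arrays = {name: seq_to_array(seq).copy() for name, seq in genome.chromosomes.items()}
    names = list(arrays)
    # sorted start/end lists per chromosome for overlap rejection
    starts: Dict[str, List[int]] = {n: [] for n in names}
    ends: Dict[str, List[int]] = {n: [] for n in names}
    for chrom, s, e in occupied or []:
        i = bisect.bisect_left(starts[chrom], s)
        starts[chrom].insert(i, s)
        ends[chrom].insert(i, e)

    records: List[RepeatRecord] = []
    consensi: Dict[str, str] = {}
    for spec in repeat_specs:
        length = spec.consensus_length
        offset = guide_offset(length)
        consensus = random_bases(length, 0.45, rng).copy()
        consensus[offset : offset + 20] = seq_to_array(guide)
        consensi[spec.element_class] = array_to_seq(consensus)
        n_exact, n_mm1, n_mm2 = _variant_counts(spec)
        weights = np.array(
            [max(genome.lengths[n] - length, 0) for n in names], dtype=float
        )
        if weights.sum() == 0:
            raise CapacityError(f"no chromosome can hold a {length} bp copy")
        weights /= weights.sum()
        for copy_index in range(spec.copy_number):
            placed = False
            for _ in range(max_attempts_per_copy):
                chrom = names[rng.choice(len(names), p=weights)]
                start = int(rng.integers(0, genome.lengths[chrom] - length + 1))
                end = start + length
                i = bisect.bisect_left(starts[chrom], end)
                if i > 0 and ends[chrom][i - 1] > start:
                    continue  # overlaps the previous interval
                starts[chrom].insert(i, start)
                ends[chrom].insert(i, end)
                placed = True
                break
            if not placed:
                raise CapacityError(
                    f"could not place copy {copy_index + 1}/{spec.copy_number} of "
                    f"{spec.element_class} ({length} bp) after "
                    f"{max_attempts_per_copy} attempts; genome too full"
                )
            copy_seq = consensus.copy()
            # divergence on non-guide positions
            if spec.divergence_rate > 0:
                mask = rng.random(length) < spec.divergence_rate
                mask[offset : offset + 20] = False
                idx = np.flatnonzero(mask)
                if len(idx):
                    shift = rng.integers(1, 4, size=len(idx)).astype(np.uint8)
                    bits = _ASCII_TO_BITS[copy_seq[idx]]
                    copy_seq[idx] = BASES[(bits + shift) % 4]
            if copy_index < n_exact:
                mm = 0
                region = guide
            elif copy_index < n_exact + n_mm1:
                mm = 1
                region = mutate_guide(guide, 1, rng)
            elif copy_index < n_exact + n_mm1 + n_mm2:
                mm = 2
                region = mutate_guide(guide, 2, rng)
            else:
                mm = -1
                region = mutate_guide(guide, 5, rng)
            copy_seq[offset : offset + 20] = seq_to_array(region)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                copy_seq = revcomp_array(copy_seq)
            arrays[chrom][start:end] = copy_seq
            records.append(
                RepeatRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    element_class=spec.element_class,
                    strand=strand,
                    copy_id=f"{spec.element_class}_{copy_index:05d}",
                    guide_mismatches=mm,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    new_genome = Genome({n: array_to_seq(a) for n, a in arrays.items()})
    return new_genome, RepeatAnnotation(records, consensi)


# ---------------------------------------------------------------------------
# binned short-read counts
# ---------------------------------------------------------------------------

def bin_grid(lengths: Dict[str, int], bin_size: int) -> Dict[str, int]:
    """Number of bins per chromosome (last bin may be short)."""
    if bin_size <= 0:
        raise SpecificationError("bin_size must be positive")
    return {c: -(-length // bin_size) for c, length in lengths.items()}


@dataclass
class BinnedCounts:
    """Per-bin integer read counts on a fixed genome grid."""

    sample_id: str
    bin_size: int
    counts: Dict[str, np.ndarray]  # chrom -> int array, one entry per bin
    chrom_lengths: Dict[str, int]

    @property
    def total_count(self) -> int:
        return int(sum(int(a.sum()) for a in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return sum(len(a) for a in self.counts.values())

    def same_grid(self, other: "BinnedCounts") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_lengths == other.chrom_lengths
            and list(self.counts) == list(other.counts)
        )


def simulate_binned_counts(
    copy_number_truth,
    depth: float,
    seed: int = 0,
    sample_id: str = "sample",
    baseline_ploidy: float = 1.0,
) -> BinnedCounts:
    """Draw per-bin counts from Poisson(depth * copy_number / baseline).

    ``copy_number_truth`` is a :class:`~gcrtools.rearrange.CopyNumberTruth`
    (or any object exposing ``bin_size``, ``chrom_lengths`` and
    ``mean_copy()`` returning chrom -> per-bin mean copy arrays).
    No alignment step is simulated: the CNV statistic downstream consumes
    per-bin match counts directly.
    """
    if depth <= 0:
        raise SpecificationError("depth must be positive")
    rng = np.random.default_rng(seed)
    counts = {}
    for chrom, copies in copy_number_truth.mean_copy().items():
        copies = np.asarray(copies, dtype=float)
        if np.any(copies < 0):
            raise DataError("negative copy numbers")
        lam = depth * copies / baseline_ploidy
        counts[chrom] = rng.poisson(lam).astype(np.int64)
    return BinnedCounts(
        sample_id=sample_id,
        bin_size=copy_number_truth.bin_size,
        counts=counts,
        chrom_lengths=dict(copy_number_truth.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

@dataclass
class LongRead:
    """A simulated long read with exact provenance.

    ``true_origin`` lists, in read order, the source-genome intervals the
    (pre-error) read was copied from: tuples of
    ``(source_chrom, start, end, strand)``.  The concatenated origin lengths
    equal the pre-error read length.
    """

    read_id: str
    sequence: str
    true_origin: List[Tuple[str, int, int, str]]
    error_rate_applied: float

    def __len__(self):
        return len(self.sequence)

    @property
    def spans_junction(self) -> bool:
        return len(self.true_origin) > 1


def _apply_errors(
    arr: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitutions (60% of errors) plus insertions/deletions (20% each)."""
    if error_rate == 0:
        return arr
    n = len(arr)
    sub = rng.random(n) < 0.6 * error_rate
    idx = np.flatnonzero(sub)
    if len(idx):
        shift = rng.integers(1, 4, size=len(idx)).astype(np.uint8)
        arr = arr.copy()
        arr[idx] = BASES[(_ASCII_TO_BITS[arr[idx]] + shift) % 4]
    dele = rng.random(n) < 0.2 * error_rate
    ins = rng.random(n) < 0.2 * error_rate
    reps = np.ones(n, dtype=np.int64) - dele + ins
    out = np.repeat(arr, reps)
    # inserted bases: the second copy of a repeated base becomes random
    if ins.any():
        pos = np.cumsum(reps) - 1  # index of last output base per input base
        ins_pos = pos[ins & ~dele]
        out[ins_pos] = BASES[rng.integers(0, 4, size=len(ins_pos))]
    return out


def simulate_long_reads(
    derivative_genome,
    n_reads: int,
    length_distribution: Tuple[float, int] = (8000.0, 500),
    error_rate: float = 0.0,
    seed: int = 0,
    read_prefix: str = "read",
) -> List[LongRead]:
    """Sample long reads uniformly from a derivative (or plain) genome.

    ``derivative_genome`` is a :class:`~gcrtools.rearrange.DerivativeGenome`;
    a plain :class:`Genome` may be passed and is treated as its own
    single-segment derivative.  Read lengths follow a gamma distribution
    (shape 2) with the given mean, truncated below at the minimum length —
    mirroring a long-read library with short reads filtered out.
    """
    from .rearrange import DerivativeGenome  # circular-import avoidance

    if n_reads < 0:
        raise SpecificationError("n_reads must be >= 0")
    if not 0 <= error_rate <= 0.2:
        raise SpecificationError("error_rate must lie in [0, 0.2]")
    if isinstance(derivative_genome, Genome):
        derivative_genome = DerivativeGenome.from_genome(derivative_genome)
    mean_len, min_len = length_distribution
    if mean_len < min_len:
        raise SpecificationError("mean read length below minimum length")
    names = derivative_genome.names
    lengths = np.array([derivative_genome.length(n) for n in names], dtype=float)
    if lengths.sum() == 0:
        raise SpecificationError("derivative genome is empty")
    weights = lengths / lengths.sum()
    rng = np.random.default_rng(seed)
    reads: List[LongRead] = []
    for i in range(n_reads):
        for _ in range(1000):
            read_len = int(rng.gamma(2.0, mean_len / 2.0))
            if read_len < min_len:
                continue
            ci = int(rng.choice(len(names), p=weights))
            chrom_len = int(lengths[ci])
            if chrom_len < min_len:
                continue
            start = int(rng.integers(0, chrom_len))
            read_len = min(read_len, chrom_len - start)
            if read_len >= min_len:
                break
        else:  # pragma: no cover - pathological derivative
            raise SpecificationError("could not draw a read of minimum length")
        name = names[ci]
        arr = derivative_genome.sequence_array(name)[start : start + read_len]
        origin = derivative_genome.origin_of(name, start, start + read_len)
        seq = _apply_errors(arr, error_rate, rng)
        reads.append(
            LongRead(
                read_id=f"{read_prefix}_{i:06d}",
                sequence=array_to_seq(seq),
                true_origin=origin,
                error_rate_applied=error_rate,
            )
        )
    return reads


def reconstruct_from_origin(read: LongRead, genome: Genome) -> str:
    """Rebuild the pre-error read sequence from its true_origin intervals."""
    parts = []
    for chrom, start, end, strand in read.true_origin:
        piece = genome.chromosomes[chrom][start:end]
        parts.append(piece if strand == "+" else revcomp(piece))
    return "".join(parts)
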