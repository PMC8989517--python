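"""Repeat-anchored translocation calling from long reads.

The strategy mirrors long-read validation of repeat-mediated
rearrangements: (1) filter reads by length (and a quality proxy when
available), (2) find reads containing a repeat-element consensus, (3) map
the element-flanking parts of each such read back to the reference, and
(4) call a translocation when the two flanks map to different chromosomal
parts — different chromosomes, far apart on one chromosome, or in
incompatible orientation.  Calls are clustered across reads and evaluated
against simulator junction truth.

Element detection uses bit-parallel infix edit-distance alignment
(``edlib``) with an identity threshold; flank mapping uses either the
builtin unique-k-mer anchor/chaining mapper (adequate for desk-scale
synthetic references with unique flanks) or split alignments imported from
a PAF file produced by a real long-read aligner.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .errors import SpecificationError
from .rearrange import Junction, TRANSLOCATION_INTER, TRANSLOCATION_INTRA, INVERSION
from .sequtils import kmer_codes, revcomp, seq_to_array
from .synthetic import Genome, LongRead


@dataclass(frozen=True)
class SplitAlignment:
    read_id: str
    read_start: int
    read_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    identity: float
    source: str  # builtin_mapper | paf_import


@dataclass(frozen=True)
class ElementHit:
    read_id: str
    read_start: int
    read_end: int
    element_class: str
    strand: str
    identity: float


@dataclass
class TranslocationCall:
    junction: Junction
    read_ids: List[str]
    element_class: str

    @property
    def support(self) -> int:
        return len(self.read_ids)


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------

def filter_reads(
    reads: Sequence[LongRead],
    min_quality_proxy: Optional[float] = None,
    min_length: int = 500,
) -> List[LongRead]:
    """Length filter (exact) plus an optional quality proxy.

    Real long-read pipelines filter on mean basecall quality (e.g. Q7);
    for simulated FASTA reads the known injected error rate serves as the
    proxy, compared as Q = -10 log10(error_rate) >= min_quality_proxy.
    Reads without any quality information pass the quality filter.
    """
    out = []
    for read in reads:
        if len(read.sequence) < min_length:
            continue
        if min_quality_proxy is not None:
            err = getattr(read, "error_rate_applied", None)
            if err is not None and err > 0:
                q = -10.0 * np.log10(err)
                if q < min_quality_proxy:
                    continue
        out.append(read)
    return out


# ---------------------------------------------------------------------------
# element detection
# ---------------------------------------------------------------------------

def _kmer_screen(read_codes: np.ndarray, consensus_codes: np.ndarray,
                 min_shared: int) -> bool:
    if len(read_codes) == 0:
        return False
    hits = np.searchsorted(consensus_codes, read_codes)
    hits = hits.clip(0, len(consensus_codes) - 1)
    return int((consensus_codes[hits] == read_codes).sum()) >= min_shared


def find_element_reads(
    reads: Sequence[LongRead],
    element_consensi: Dict[str, str],
    min_identity: float = 0.8,
    min_span: int = 100,
    tile: int = 100,
    merge_gap: int = 60,
    screen_k: int = 13,
    screen_min_shared: int = 3,
) -> List[ElementHit]:
    """Read intervals matching an element consensus, by tiled infix
    alignment.

    The consensus is split into ~``tile``-bp tiles which are aligned
    (both orientations) inside each read with bit-parallel edit-distance
    alignment; tile hits with identity >= min_identity are merged (gap up
    to ``merge_gap``) into element intervals of span >= min_span.  Tiling
    is essential at rearrangement junctions, where a read carries a
    *chimeric* element — two halves of different copies, possibly in
    opposite orientations — that a full-length consensus alignment would
    miss.  A shared k-mer screen skips reads that cannot contain the
    element.  One hit per merged interval per (read, class) is returned.
    """
    prepared = {}
    for cls, consensus in element_consensi.items():
        rc = revcomp(consensus)
        codes = np.unique(np.concatenate([
            kmer_codes(seq_to_array(consensus), screen_k),
            kmer_codes(seq_to_array(rc), screen_k)]))
        tiles = []
        n_tiles = max(1, round(len(consensus) / tile))
        bounds = np.linspace(0, len(consensus), n_tiles + 1).astype(int)
        for strand, seq in (("+", consensus), ("-", rc)):
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a >= 30:
                    tiles.append((strand, seq[a:b]))
        prepared[cls] = (codes, tiles)
    hits: List[ElementHit] = []
    for read in reads:
        arr = seq_to_array(read.sequence)
        read_codes = kmer_codes(arr, screen_k)
        for cls, (codes, tiles) in prepared.items():
            if not _kmer_screen(read_codes, codes, screen_min_shared):
                continue
            tile_hits = []  # (start, end, identity, strand)
            for strand, query in tiles:
                max_dist = int(len(query) * (1.0 - min_identity)) + 1
                aln = edlib.align(query, read.sequence, mode="HW",
                                  task="locations", k=max_dist)
                if aln["editDistance"] < 0:
                    continue
                for loc in aln["locations"]:
                    if loc[0] is None:
                        continue
                    span = loc[1] - loc[0] + 1
                    identity = 1.0 - aln["editDistance"] / max(span, len(query))
                    if identity >= min_identity:
                        tile_hits.append((loc[0], loc[1] + 1, identity, strand))
            if not tile_hits:
                continue
            tile_hits.sort()
            merged = []  # [start, end, [identities], [strands]]
            for s, e, ident, strand in tile_hits:
                if merged and s <= merged[-1][1] + merge_gap:
                    merged[-1][1] = max(merged[-1][1], e)
                    merged[-1][2].append(ident)
                    merged[-1][3].append(strand)
                else:
                    merged.append([s, e, [ident], [strand]])
            for s, e, idents, strands in merged:
                if e - s >= min_span:
                    strand = max(set(strands), key=strands.count)
                    hits.append(ElementHit(read.read_id, s, e, cls, strand,
                                           float(np.mean(idents))))
    return hits


# ---------------------------------------------------------------------------
# builtin flank mapper
# ---------------------------------------------------------------------------

class KmerIndex:
    """Unique-k-mer index of a reference genome.

    K-mers occurring more than once anywhere in the reference are dropped,
    so anchors are unambiguous; chaining tolerates a small diagonal band.
    """

    def __init__(self, genome: Genome, k: int = 15):
        if k < 4 or k > 31:
            raise SpecificationError("k must lie in [4, 31]")
        if min(genome.lengths.values()) < k:
            raise SpecificationError("reference smaller than k")
        self.k = k
        self.chrom_names = genome.names
        codes_all = []
        pos_all = []
        chrom_all = []
        for ci, name in enumerate(self.chrom_names):
            arr = seq_to_array(genome.chromosomes[name])
            codes = kmer_codes(arr, k)
            codes_all.append(codes)
            pos_all.append(np.arange(len(codes), dtype=np.int64))
            chrom_all.append(np.full(len(codes), ci, dtype=np.int32))
        codes = np.concatenate(codes_all)
        pos = np.concatenate(pos_all)
        chrom = np.concatenate(chrom_all)
        order = np.argsort(codes, kind="stable")
        codes, pos, chrom = codes[order], pos[order], chrom[order]
        # keep k-mers occurring exactly once
        uniq = np.ones(len(codes), dtype=bool)
        if len(codes) > 1:
            dup = codes[1:] == codes[:-1]
            uniq[1:] &= ~dup
            uniq[:-1] &= ~dup
        self.codes = codes[uniq]
        self.pos = pos[uniq]
        self.chrom = chrom[uniq]

    def lookup(self, query_codes: np.ndarray):
        """(query_index, chrom_index, ref_pos) arrays of unique-k-mer hits."""
        if len(query_codes) == 0 or len(self.codes) == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        idx = np.searchsorted(self.codes, query_codes).clip(
            0, len(self.codes) - 1)
        found = self.codes[idx] == query_codes
        qi = np.flatnonzero(found)
        return qi, self.chrom[idx[qi]].astype(np.int64), self.pos[idx[qi]]


def _best_chain(qi, chrom, rpos, strand: str, flank_len: int, k: int,
                band: int = 50):
    """Largest co-diagonal anchor group; returns (n_anchors, chrom_index,
    read_lo, read_hi, ref_lo, ref_hi) or None."""
    if len(qi) == 0:
        return None
    diag = rpos - qi if strand == "+" else rpos + qi
    keys = chrom * (1 << 40) + (diag // band)
    best = None
    for key in np.unique(keys):
        sel = keys == key
        n = int(sel.sum())
        if best is None or n > best[0]:
            q = qi[sel]
            r = rpos[sel]
            best = (n, int(chrom[sel][0]), int(q.min()), int(q.max()) + k,
                    int(r.min()), int(r.max()) + k)
    return best


def map_flanks(
    read: LongRead,
    element_hit: ElementHit,
    reference: Genome,
    index: Optional[KmerIndex] = None,
    k: int = 15,
    min_flank: int = 200,
    min_anchors: int = 5,
) -> List[SplitAlignment]:
    """Map the element-flanking parts of a read with the builtin mapper.

    Each flank (the read outside the element hit) of at least ``min_flank``
    bases is anchored by unique reference k-mers and chained per
    (chromosome, strand, diagonal band); the best chain per flank is
    reported with identity estimated from anchor density
    (density ** (1/k), the per-base accuracy implied by exact-k-mer
    survival).
    """
    if index is None:
        index = KmerIndex(reference, k=k)
    k = index.k
    flanks = []
    if element_hit.read_start >= min_flank:
        flanks.append(("left", 0, element_hit.read_start))
    if len(read.sequence) - element_hit.read_end >= min_flank:
        flanks.append(("right", element_hit.read_end, len(read.sequence)))
    out = []
    for _, lo, hi in flanks:
        seq = read.sequence[lo:hi]
        best = None
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            codes = kmer_codes(seq_to_array(query), k)
            qi, chrom, rpos = index.lookup(codes)
            chain = _best_chain(qi, chrom, rpos, "+", len(query), k)
            if chain is None or chain[0] < min_anchors:
                continue
            n, ci, qlo, qhi, rlo, rhi = chain
            if strand == "-":  # map back to forward read coordinates
                qlo, qhi = len(query) - qhi, len(query) - qlo
            density = n / max(qhi - qlo - k + 1, 1)
            identity = min(1.0, density ** (1.0 / k))
            cand = SplitAlignment(
                read_id=read.read_id,
                read_start=lo + qlo,
                read_end=lo + qhi,
                target_chrom=index.chrom_names[ci],
                target_start=rlo,
                target_end=rhi,
                strand=strand,
                identity=identity,
                source="builtin_mapper",
            )
            if best is None or n > best[0]:
                best = (n, cand)
        if best is not None:
            out.append(best[1])
    return out


# ---------------------------------------------------------------------------
# PAF import
# ---------------------------------------------------------------------------

def read_paf(path) -> List[SplitAlignment]:
    """Import split alignments from a PAF file (12 mandatory columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            matches, block = int(f[9]), int(f[10])
            out.append(SplitAlignment(
                read_id=f[0],
                read_start=int(f[2]),
                read_end=int(f[3]),
                target_chrom=f[5],
                target_start=int(f[7]),
                target_end=int(f[8]),
                strand=f[4],
                identity=matches / block if block else 0.0,
                source="paf_import",
            ))
    return out


# ---------------------------------------------------------------------------
# calling and evaluation
# ---------------------------------------------------------------------------

def _flank_breakpoints(hit: ElementHit, left: SplitAlignment,
                       right: SplitAlignment):
    """Element-proximal reference coordinates of the two flank alignments."""
    bp_left = left.target_end if left.strand == "+" else left.target_start
    bp_right = right.target_start if right.strand == "+" else right.target_end
    return bp_left, bp_right


def call_translocations(
    element_hits: Sequence[ElementHit],
    split_alignments: Sequence[SplitAlignment],
    min_flank: int = 200,
    min_distance: int = 100_000,
    min_support: int = 1,
    cluster_window: int = 500,
    slop: int = 50,
    abut: int = 150,
) -> List[TranslocationCall]:
    """Call translocations from element-containing reads with mapped flanks.

    A read votes for a junction when its element hit is flanked by
    alignments on both sides that land on different chromosomes, more than
    ``min_distance`` apart on one chromosome, or in incompatible
    orientation.  A flank alignment must end within ``abut`` bases of the
    element hit in read coordinates — a chain that stops short of the
    element (e.g. at a second junction inside the flank) does not localise
    this element's junction.  Per-read votes are clustered within
    ``cluster_window`` bp on both ends and reported with accumulated
    support.
    """
    by_read: Dict[str, List[SplitAlignment]] = {}
    for a in split_alignments:
        by_read.setdefault(a.read_id, []).append(a)
    votes = []  # (chromA, posA, strandA, chromB, posB, strandB, class, read, cls)
    for hit in element_hits:
        alns = by_read.get(hit.read_id, [])
        lefts = [a for a in alns
                 if a.read_end <= hit.read_start + slop
                 and a.read_end >= hit.read_start - abut
                 and a.read_end - a.read_start >= min_flank]
        rights = [a for a in alns
                  if a.read_start >= hit.read_end - slop
                  and a.read_start <= hit.read_end + abut
                  and a.read_end - a.read_start >= min_flank]
        if not lefts or not rights:
            continue
        left = max(lefts, key=lambda a: a.read_end - a.read_start)
        right = max(rights, key=lambda a: a.read_end - a.read_start)
        bp_l, bp_r = _flank_breakpoints(hit, left, right)
        if left.target_chrom != right.target_chrom:
            jclass = TRANSLOCATION_INTER
        elif left.strand != right.strand:
            jclass = INVERSION
        elif abs(bp_l - bp_r) > min_distance:
            jclass = TRANSLOCATION_INTRA
        else:
            continue  # intact element locus, no call
        votes.append((left.target_chrom, bp_l, left.strand,
                      right.target_chrom, bp_r, right.strand,
                      jclass, hit.read_id, hit.element_class))
    # canonical end ordering then greedy clustering
    order: Dict[str, int] = {}
    for v in votes:
        for c in (v[0], v[3]):
            order.setdefault(c, len(order))
    canon = []
    for cA, pA, sA, cB, pB, sB, jc, rid, cls in votes:
        if (order[cB], pB) < (order[cA], pA):
            cA, pA, sA, cB, pB, sB = cB, pB, sB, cA, pA, sA
        canon.append((cA, pA, sA, cB, pB, sB, jc, rid, cls))
    canon.sort(key=lambda v: (v[0], v[3], v[1], v[4]))
    clusters: List[List[tuple]] = []
    for v in canon:
        placed = False
        for cl in clusters:
            ref = cl[0]
            if (v[0] == ref[0] and v[3] == ref[3]
                    and abs(v[1] - ref[1]) <= cluster_window
                    and abs(v[4] - ref[4]) <= cluster_window):
                cl.append(v)
                placed = True
                break
        if not placed:
            clusters.append([v])
    calls = []
    for cl in clusters:
        if len(cl) < min_support:
            continue
        posA = int(round(np.median([v[1] for v in cl])))
        posB = int(round(np.median([v[4] for v in cl])))
        ref = cl[0]
        junction = Junction(ref[0], posA, ref[2], ref[3], posB, ref[5],
                            ref[6], support=len(cl))
        calls.append(TranslocationCall(
            junction=junction,
            read_ids=[v[7] for v in cl],
            element_class=cl[0][8],
        ))
    return calls


def evaluate_calls(
    calls: Sequence[TranslocationCall],
    truth_junctions: Sequence[Junction],
    tolerance: int = 500,
) -> Tuple[float, float, List[dict]]:
    """Greedy 1-1 matching of calls to truth within a distance tolerance.

    Ends are matched unordered (a call may report the pair either way
    round).  Returns (precision, recall, per-junction table).
    """
    def end_distance(call: Junction, truth: Junction) -> float:
        d1 = d2 = np.inf
        if call.chromA == truth.chromA and call.chromB == truth.chromB:
            d1 = max(abs(call.posA - truth.posA), abs(call.posB - truth.posB))
        if call.chromA == truth.chromB and call.chromB == truth.chromA:
            d2 = max(abs(call.posA - truth.posB), abs(call.posB - truth.posA))
        return min(d1, d2)

    pairs = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truth_junctions):
            d = end_distance(c.junction, t)
            if d <= tolerance:
                pairs.append((d, i, j))
    pairs.sort()
    used_c, used_t = set(), set()
    matches = {}
    for d, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        matches[j] = (i, d)
    precision = len(used_c) / len(calls) if calls else 0.0
    recall = len(used_t) / len(truth_junctions) if truth_junctions else 0.0
    table = []
    for j, t in enumerate(truth_junctions):
        entry = {"chromA": t.chromA, "posA": t.posA, "chromB": t.chromB,
                 "posB": t.posB, "junction_class": t.junction_class,
                 "matched": j in matches}
        if j in matches:
            i, d = matches[j]
            entry["call_support"] = calls[i].support
            entry["distance"] = d
        table.append(entry)
    return precision, recall, table
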