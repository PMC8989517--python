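"""Long-read filtering, element detection, flank mapping and
translocation calling."""
import subprocess

import numpy as np
import pytest

from gcrtools import (
    GenomeSpec,
    KmerIndex,
    LongRead,
    call_translocations,
    evaluate_calls,
    filter_reads,
    find_element_reads,
    generate_genome,
    map_flanks,
    read_paf,
    simulate_long_reads,
)
from gcrtools.longread import ElementHit, SplitAlignment
from gcrtools.sequtils import revcomp
from gcrtools.rearrange import Junction


def make_read(read_id, sequence, error=0.0):
    return LongRead(read_id, sequence, [], error)


class TestFilterReads:
    @pytest.mark.parametrize("length,kept", [(499, False), (500, True)])
    def test_length_boundary(self, length, kept):
        reads = [make_read("r", "A" * length)]
        assert bool(filter_reads(reads)) is kept

    def test_quality_proxy_from_error_rate(self):
        # Q7 corresponds to an error rate of 0.2: 0.05 is Q13, 0.25 is Q6
        good = make_read("good", "A" * 600, error=0.05)
        bad = make_read("bad", "A" * 600, error=0.25)
        kept = filter_reads([good, bad], min_quality_proxy=7.0)
        assert [r.read_id for r in kept] == ["good"]

    def test_count_matches_direct_scan(self, rng):
        reads = [make_read(f"r{i}", "A" * int(rng.integers(300, 900)))
                 for i in range(200)]
        kept = filter_reads(reads)
        assert len(kept) == sum(1 for r in reads if len(r.sequence) >= 500)


class TestFindElementReads:
    def consensus(self, seed=0, length=300):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=length))

    def test_pure_consensus_read_is_hit(self):
        consensus = self.consensus()
        read = make_read("r0", consensus)
        hits = find_element_reads([read], {"Alu_like": consensus})
        assert len(hits) == 1
        assert hits[0].read_start == 0 and hits[0].read_end == 300

    def test_reverse_complement_detected(self):
        consensus = self.consensus(1)
        read = make_read("r0", revcomp(consensus))
        hits = find_element_reads([read], {"Alu_like": consensus})
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_no_hits_on_random_megabase(self):
        genome = generate_genome(GenomeSpec(1, (1_000_000,), 0.45, seed=3))
        reads = simulate_long_reads(genome, 125, (8_000, 500), 0.0, seed=4)
        consensus = self.consensus(2)
        assert find_element_reads(reads, {"Alu_like": consensus}) == []

    def test_detected_at_ten_percent_error(self):
        consensus = self.consensus(5, length=600)
        rng = np.random.default_rng(6)
        noisy = list(consensus)
        for i in rng.choice(600, size=60, replace=False):
            noisy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[i]]
        pad = "".join(rng.choice(list("ACGT"), size=400))
        read = make_read("r0", pad + "".join(noisy) + pad)
        hits = find_element_reads([read], {"L1_like": consensus},
                                  min_identity=0.8)
        assert len(hits) == 1
        assert hits[0].identity >= 0.8
        assert abs(hits[0].read_start - 400) < 50

    def test_chimeric_halves_detected_as_one_interval(self):
        """A junction read carries two half-elements, the right one
        inverted; the merged hit must still cover the chimera."""
        consensus = self.consensus(7, length=400)
        rng = np.random.default_rng(8)
        pad1 = "".join(rng.choice(list("ACGT"), size=500))
        pad2 = "".join(rng.choice(list("ACGT"), size=500))
        chimera = consensus[:200] + revcomp(consensus[:200])
        read = make_read("r0", pad1 + chimera + pad2)
        hits = find_element_reads([read], {"Alu_like": consensus},
                                  min_span=100)
        assert len(hits) == 1
        assert hits[0].read_start == pytest.approx(500, abs=60)
        assert hits[0].read_end == pytest.approx(900, abs=60)


@pytest.fixture(scope="module")
def reference():
    return generate_genome(GenomeSpec(2, (120_000, 80_000), 0.45, seed=9))


@pytest.fixture(scope="module")
def index(reference):
    return KmerIndex(reference)


class TestMapFlanks:
    def test_exact_flank_chains_at_true_locus(self, reference, index):
        flank = reference.chromosomes["chr1"][30_000:34_000]
        read = make_read("r0", flank + "T" * 400)
        hit = ElementHit("r0", 4_000, 4_400, "Alu_like", "+", 1.0)
        alns = map_flanks(read, hit, reference, index=index)
        assert len(alns) == 1
        a = alns[0]
        assert a.target_chrom == "chr1" and a.strand == "+"
        assert a.read_end - a.read_start >= 0.95 * 4_000
        assert abs(a.target_start - 30_000) < 50
        assert a.identity > 0.99

    def test_reverse_flank_strand(self, reference, index):
        flank = revcomp(reference.chromosomes["chr2"][10_000:13_000])
        read = make_read("r0", "T" * 400 + flank)
        hit = ElementHit("r0", 0, 400, "Alu_like", "+", 1.0)
        alns = map_flanks(read, hit, reference, index=index)
        assert len(alns) == 1
        assert alns[0].strand == "-"
        assert alns[0].target_chrom == "chr2"

    def test_random_flank_finds_no_chain(self, reference, index, rng):
        junk = "".join(rng.choice(list("ACGT"), size=3_000))
        read = make_read("r0", junk + "T" * 400)
        hit = ElementHit("r0", 3_000, 3_400, "Alu_like", "+", 1.0)
        assert map_flanks(read, hit, reference, index=index) == []

    def test_flanks_from_two_chromosomes(self, reference, index):
        left = reference.chromosomes["chr1"][5_000:8_000]
        right = reference.chromosomes["chr2"][40_000:43_000]
        read = make_read("r0", left + "T" * 400 + right)
        hit = ElementHit("r0", 3_000, 3_400, "Alu_like", "+", 1.0)
        alns = map_flanks(read, hit, reference, index=index)
        assert {a.target_chrom for a in alns} == {"chr1", "chr2"}


class TestCalling:
    def test_intact_locus_is_not_called(self):
        hit = ElementHit("r0", 2_000, 2_300, "Alu_like", "+", 1.0)
        left = SplitAlignment("r0", 0, 2_000, "chr1", 50_000, 52_000, "+",
                              1.0, "builtin_mapper")
        right = SplitAlignment("r0", 2_300, 4_300, "chr1", 52_300, 54_300,
                               "+", 1.0, "builtin_mapper")
        assert call_translocations([hit], [left, right]) == []

    def test_interchromosomal_flanks_are_called(self):
        hit = ElementHit("r0", 2_000, 2_300, "Alu_like", "+", 1.0)
        left = SplitAlignment("r0", 0, 2_000, "chr1", 50_000, 52_000, "+",
                              1.0, "builtin_mapper")
        right = SplitAlignment("r0", 2_300, 4_300, "chr2", 9_000, 11_000,
                               "+", 1.0, "builtin_mapper")
        calls = call_translocations([hit], [left, right])
        assert len(calls) == 1
        assert calls[0].junction.junction_class == "translocation_inter"

    def test_votes_cluster_across_reads(self, rearranged_scene):
        """>=90% of simulated junction-spanning reads over one
        inter-chromosomal junction collapse into a single call."""
        genome = rearranged_scene["genome"]
        derivative = rearranged_scene["derivative"]
        annotation = rearranged_scene["annotation"]
        inter = [j for j in rearranged_scene["junctions"] if j.is_inter]
        assert inter
        reads = simulate_long_reads(derivative, 2_000, (6_000, 500), 0.05,
                                    seed=20)
        hits = find_element_reads(reads, dict(annotation.consensi))
        index = KmerIndex(genome)
        by_id = {r.read_id: r for r in reads}
        alignments = []
        for h in hits:
            alignments.extend(map_flanks(by_id[h.read_id], h, genome,
                                         index=index))
        calls = call_translocations(hits, alignments)
        inter_calls = [c for c in calls
                       if c.junction.junction_class == "translocation_inter"]
        precision, recall, _ = evaluate_calls(inter_calls, inter)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_evaluation_boundary_and_degenerate_cases(self):
        truth = [Junction("chr1", 1_000, "+", "chr2", 2_000, "-",
                          "translocation_inter")]
        exact = [make_call("chr1", 1_000, "chr2", 2_000)]
        shifted = [make_call("chr1", 1_499, "chr2", 2_499)]
        too_far = [make_call("chr1", 1_501, "chr2", 2_000)]
        assert evaluate_calls(exact, truth)[:2] == (1.0, 1.0)
        assert evaluate_calls(shifted, truth, tolerance=500)[:2] == (1.0, 1.0)
        assert evaluate_calls(too_far, truth, tolerance=500)[:2] == (0.0, 0.0)
        assert evaluate_calls([], truth)[:2] == (0.0, 0.0)


def make_call(chromA, posA, chromB, posB):
    from gcrtools import TranslocationCall
    return TranslocationCall(
        Junction(chromA, posA, "+", chromB, posB, "-",
                 "translocation_inter", support=1),
        ["r0"], "Alu_like")


class TestPafAgreement:
    def test_paf_import_roundtrip(self, tmp_path):
        line = "r0\t4000\t0\t2000\t+\tchr1\t120000\t50000\t52000\t1990\t2000\t60\n"
        path = tmp_path / "aln.paf"
        path.write_text(line)
        alns = read_paf(path)
        assert len(alns) == 1
        a = alns[0]
        assert (a.read_id, a.target_chrom, a.strand) == ("r0", "chr1", "+")
        assert a.identity == pytest.approx(0.995)
        assert a.source == "paf_import"

    def test_builtin_mapper_agrees_with_minimap2_calls(self, tmp_path,
                                                       rearranged_scene):
        """Error-free reads: calls from builtin-mapper flank alignments
        equal calls from minimap2 PAF alignments of the same flanks."""
        import shutil
        minimap2 = shutil.which("minimap2")
        assert minimap2, "minimap2 is required for this cross-check"
        genome = rearranged_scene["genome"]
        derivative = rearranged_scene["derivative"]
        annotation = rearranged_scene["annotation"]
        reads = simulate_long_reads(derivative, 600, (6_000, 500), 0.0,
                                    seed=21)
        hits = find_element_reads(reads, dict(annotation.consensi))
        by_id = {r.read_id: r for r in reads}
        index = KmerIndex(genome)
        builtin = []
        flank_records = []
        for h in hits:
            builtin.extend(map_flanks(by_id[h.read_id], h, genome,
                                      index=index))
            read = by_id[h.read_id]
            if h.read_start >= 200:
                flank_records.append((f"{h.read_id}", 0, h.read_start,
                                      read.sequence[:h.read_start]))
            if len(read.sequence) - h.read_end >= 200:
                flank_records.append((f"{h.read_id}", h.read_end,
                                      len(read.sequence),
                                      read.sequence[h.read_end:]))
        ref_fa = tmp_path / "ref.fa"
        with open(ref_fa, "w") as fh:
            for name, seq in genome.chromosomes.items():
                fh.write(f">{name}\n{seq}\n")
        flank_fa = tmp_path / "flanks.fa"
        with open(flank_fa, "w") as fh:
            for rid, lo, hi, seq in flank_records:
                fh.write(f">{rid}__{lo}_{hi}\n{seq}\n")
        paf_path = tmp_path / "flanks.paf"
        with open(paf_path, "w") as fh:
            subprocess.run([minimap2, "-x", "map-ont", "--secondary=no",
                            str(ref_fa), str(flank_fa)],
                           stdout=fh, stderr=subprocess.DEVNULL, check=True)
        imported = []
        for a in read_paf(paf_path):
            rid, span = a.read_id.rsplit("__", 1)
            lo, hi = map(int, span.split("_"))
            imported.append(SplitAlignment(
                rid, lo + a.read_start, lo + a.read_end, a.target_chrom,
                a.target_start, a.target_end, a.strand, a.identity,
                "paf_import"))
        calls_builtin = call_translocations(hits, builtin)
        calls_paf = call_translocations(hits, imported)

        def call_keys(calls, tol=500):
            return {(c.junction.chromA, round(c.junction.posA / tol),
                     c.junction.chromB, round(c.junction.posB / tol),
                     c.junction.junction_class)
                    for c in calls
                    if c.junction.junction_class == "translocation_inter"}

        assert call_keys(calls_builtin) == call_keys(calls_paf)
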