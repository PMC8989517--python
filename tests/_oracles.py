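"""Naive reference implementations used only as test oracles.

Deliberately simple (pure-Python loops, brute force) and independent of
the production code paths they are compared against.
"""

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq):
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def naive_guide_scan(chromosomes, guide, max_mismatch, require_pam=False):
    """Per-window Hamming scan on both strands; returns sorted tuples of
    (chrom, pos, strand, mismatches, protospacer-oriented sequence)."""
    results = []
    targets = {"+": guide, "-": naive_revcomp(guide)}
    for chrom, seq in chromosomes.items():
        n = len(seq)
        for pos in range(n - 19):
            window = seq[pos:pos + 20]
            for strand, pattern in targets.items():
                mm = sum(1 for a, b in zip(window, pattern) if a != b)
                if mm > max_mismatch:
                    continue
                if require_pam:
                    if strand == "+":
                        if pos + 23 > n or seq[pos + 21:pos + 23] != "GG":
                            continue
                    else:
                        if pos < 3 or seq[pos - 3:pos - 1] != "CC":
                            continue
                matched = window if strand == "+" else naive_revcomp(window)
                results.append((chrom, pos, strand, mm, matched))
    return sorted(results)


def naive_count_breakpoints(junctions, regions, counting):
    """O(n*m) double loop over breakpoints x region intervals."""
    def inside(chrom, pos):
        return any(c == chrom and s <= pos < e for c, s, e in regions)

    if counting == "per_breakpoint":
        total = 0
        for j in junctions:
            total += inside(j.chromA, j.posA)
            total += inside(j.chromB, j.posB)
        return total
    total = 0
    for j in junctions:
        if inside(j.chromA, j.posA) or inside(j.chromB, j.posB):
            total += 1
    return total


def bitmap_intersection(intervals_a, intervals_b, chrom_lengths):
    """Per-base boolean intersection of two interval sets, returned as
    merged intervals."""
    out = []
    for chrom, length in chrom_lengths.items():
        a = bytearray(length)
        b = bytearray(length)
        for c, s, e in intervals_a:
            if c == chrom:
                for i in range(s, e):
                    a[i] = 1
        for c, s, e in intervals_b:
            if c == chrom:
                for i in range(s, e):
                    b[i] = 1
        start = None
        for i in range(length + 1):
            on = i < length and a[i] and b[i]
            if on and start is None:
                start = i
            elif not on and start is not None:
                out.append((chrom, start, i))
                start = None
    return sorted(out)


def naive_substring_count(chromosomes, pattern):
    """Overlapping occurrences of a pattern on both strands."""
    rc = naive_revcomp(pattern)
    total = 0
    for seq in chromosomes.values():
        for probe in {pattern, rc}:
            start = 0
            while True:
                i = seq.find(probe, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total
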