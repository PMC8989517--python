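# Methods

`gcrtools` models and analyses global chromosome rearrangement (GCR):
the state of a genome after CRISPR–Cas9 has been directed at a highly
repetitive target — conserved segments of LINE-1 (L1, ~6 kb) or Alu
(~300 bp) retrotransposons — so that hundreds to hundreds of thousands of
double-strand breaks (DSBs) are produced at once and repaired by
non-homologous end joining (NHEJ). The package couples a fully
ground-truthed simulator of this process with the statistics used to
characterise such genomes. Everything below is computed by the code; no
empirical claim is made that the tests and the reproduction script do not
themselves measure.

## Synthetic genome and repeat model

A genome is drawn i.i.d. per base with a configurable GC fraction
(default 0.41, matching the human average) over a configurable set of
chromosomes. The default scale is 4 chromosomes x 2.5 Mb = 10 Mb, with
the CNV bin size scaled from 500 kb (appropriate to a 3 Gb genome) to
50 kb; scale factors are configuration, not code.

Repeat families are embedded as full-length consensus copies placed
uniformly at non-overlapping positions on random strands. Each copy is
diverged from the consensus by i.i.d. substitutions (default 5% for
L1-like, 10% for Alu-like — younger elements are more homogeneous, but
here the values mainly set the difficulty of element detection and the
uniqueness of flanking k-mers). A 20-nt guide is written at a fixed
offset (one third of the consensus length) into a declared fraction of
copies: exactly matching, or carrying 1 or 2 substitutions; remaining
copies receive a 5-mismatch variant so they can never be counted as cut
sites. Because real repeat annotations are dominated by truncated
fragments, literal per-Mb copy counts cannot be preserved with
full-length consensi at desk scale; the defaults instead preserve the
qualitative study conditions — the short-element guide has roughly an
order of magnitude more exact sites than the long-element guide
(~120 vs ~15 on 10 Mb), and ~5% of the genome is repetitive. All copies
are treated identically (no truncation model).

The negative-control guide (`sgNC`, a sequence absent from the genome)
is carried through the whole pipeline and must produce zero cuts, zero
junctions and a null CNV profile; this is asserted by the test suite.

## Guide matching-site enumeration

`find_guide_matches` reports every 20-bp window, on either strand, whose
Hamming distance to the guide is at most 0, 1 or 2 — the raw
sequence-census semantics of an exhaustive short-read aligner in
report-all-alignments mode, which is how multi-target guides are sized.
PAM filtering is off by default for exactly that reason and available as
an option (`NGG` 3' of the protospacer, strand-aware: `CCN` immediately
5' of a minus-strand window in forward coordinates). A minus-strand
match at forward window start p is reported with `protospacer_start = p`
and the protospacer-oriented (reverse-complemented) sequence. Ambiguous
bases never match. The production scan is a chunked vectorised
sliding-window comparison; its contract — exact set equality with a
naive per-window Hamming oracle — is enforced in the tests on both
hand-written and randomised genomes, and again at acceptance scale
against a second, independently coded shifted-accumulation oracle.

## Cut-and-rejoin model

**Cuts.** Each matching site is cleaved independently with probability
`cut_probability` (default 0.25); an optional `max_cuts` cap subsamples
uniformly. The cut coordinate is `protospacer_start + cut_offset` in the
protospacer frame (default 17/20, i.e. the canonical blunt Cas9 cut 3 bp
from the PAM-proximal end), mapped to forward-strand coordinates.

**Segment fate.** Chromosomes are split at their cuts. Interior
segments (cut on both sides) are lost with probability 0.05 or
duplicated with probability 0.05; telomere-bearing segments are never
lost, since they must anchor derivative chromosomes. Every cut end is
blunt-resected by a uniform 0–10 bp.

**Rejoining.** Free ends are paired sequentially: a random free end
draws a partner with weight `intra_bias * exp(-d / distance_scale)` for
same-chromosome ends at distance d (defaults 0.7 and 500 kb) and weight
`1 - intra_bias` for other-chromosome ends. This produces the strong
intra-chromosomal, near-diagonal junction preference NHEJ shows in
practice; increasing `intra_bias` monotonically increases the intra
fraction (property-tested). Pairing is sequential random matching, not a
global optimum — O(n^2) worst case, negligible at desk scale. One
constraint is imposed: the last two telomere-anchored free ends never
join each other while unanchored chains remain, otherwise a chain could
be stranded without telomeres (an acentric circle); under this rule
every derivative chromosome provably ends in two original telomeric
ends, and with loss = dup = resection = 0 the derivative genome is an
exact permutation/reorientation of the source segments.

**Junction classes.** Junction strands follow breakend convention ('+'
= retained sequence approaches the junction in source-forward
direction). Classification is geometric: different chromosomes →
`translocation_inter`; a join involving a duplicated segment copy →
`duplication`; equal strands on one chromosome → `inversion`; opposite
strands rejoining the two (possibly resected) sides of a single cut →
perfect religation (no junction) or `deletion`; anything else →
`translocation_intra`. Downstream statistics follow the coarser
field convention and treat every non-inter class as intra-chromosomal.
Junction sequences are clean or resected blunt joins; no microhomology
model is applied.

**Copy-number truth.** Truth is kept on the source coordinate frame as
exact per-bin integer base sums: baseline 1, minus lost segments and
resected slivers, plus duplicated segments. The invariant that this
equals the per-base coverage recomputed independently from the final
derivative segment maps — for every bin, exactly — is asserted in the
tests and re-measured at acceptance scale (10 Mb, 200 cuts).

## Binned CNV analysis

Per-bin counts are simulated directly as Poisson(depth x copy/ploidy)
on the truth grid; no read alignment is simulated because the CNV
statistic consumes per-bin match counts, and an alignment stage would
exercise an external tool rather than any computation of interest.

`cnv_difference` is normalized_count(sample) − normalized_count(control)
per bin. Library-size normalization (scale both samples to the mean
library size) is the default, since raw match-count differences are only
comparable for depth-matched libraries; `none` reproduces raw
differencing and is exactly antisymmetric.

"High-CNV" bins have no canonical definition; the default rule is
scale-free — |value| strictly above its 95th percentile across bins,
adjacent qualifying bins merged — with an absolute z-score rule as the
alternative. Under the default conditions (depth 100/bin, |Δcopy| ≥ 1,
≤ 5% of bins changed) the rank rule recovers changed bins with
sensitivity ≥ 0.9 and FDR ≤ 0.1 (measured over 20 simulations).
`common_regions` intersects two region sets base-by-base. Correlation
between two CNV profiles is an ordinary least-squares fit, per bin or on
per-chromosome sums. `interval_coverage_ratio` reports mean depth of
one interval relative to another (e.g. a cassette's central region
against an intact marker on the same construct) and raises on a
zero-coverage denominator.

## Breakpoint statistics

**Permutation enrichment.** The overlap statistic T counts junction
ends (default; `per_junction` counts a junction once if either end
lands) inside a region set. Regions are re-placed uniformly at random
1000 times, genome-wide and length-preserved, without overlap among
placed intervals (bedtools-shuffle-like semantics); breakpoints stay
fixed. A one-sided upper P is reported from the continuity-corrected
normal approximation z = (T_obs − ½ − μ̂)/σ̂ — T is a discrete count, and
the uncorrected normal tail is measurably anticonservative at null means
of a few dozen — alongside the exact empirical permutation P
(1 + #{T ≥ T_obs})/(n + 1). Degenerate inputs (no junctions, zero null
variance) report p = 1 with a flag. Calibration is verified directly:
with breakpoints independent of regions covering 10% of the genome, the
nominal-5% rejection rate over 500 replicate datasets lies in
[0.03, 0.07], and with 2x-enriched breakpoints power exceeds 0.9.

**Intra/inter Monte-Carlo null.** Per run, as many endpoint pairs as
observed junctions are drawn with each endpoint uniform over the genome
(chromosome proportional to length); averages over 10 runs give expected
intra/inter counts, compared to observed by a chi-square goodness-of-fit
test with 1 df, no continuity correction. The exact null intra fraction
Σᵢ(Lᵢ/L)² is reported alongside and the simulation is checked against it
(within 3 SE at 10⁵ pairs) for several length vectors including the
degenerate single-chromosome (=1) and two-equal-chromosome (=0.5) cases.

**Nearest-element distances.** For each breakpoint, the gap to the
closest same-chromosome element of a class (0 inside an element),
bucketed into the conventional categories (<1 kb, 1–10 kb, 10–100 kb,
>100 kb, none-on-chromosome). Equality with an exhaustive scan is
asserted on 10³ x 10³ random configurations.

**Linearization.** Junctions become single (x, y) points on the
concatenated genome, end A being the smaller (chromosome-order index,
position); no symmetric double emission.

## Long-read translocation calling

The strategy mirrors long-read validation of repeat-mediated
rearrangements: find reads containing the element, map the element
flanks, call when the flanks disagree about where they are.

* **Filtering:** length ≥ 500 bp exactly; mean-quality proxy when
  available. Simulated FASTA reads carry no base qualities, so the known
  injected error rate stands in, converted as Q = −10·log₁₀(e) and
  compared to the threshold (Q7-equivalent ≈ e = 0.2).
* **Element detection:** the consensus is split into ~100 bp tiles,
  each aligned in both orientations inside the read by bit-parallel
  infix edit-distance alignment (edlib); tile hits at identity ≥ 0.8
  are merged (gap ≤ 60 bp) into element intervals of span ≥ 100 bp.
  Tiling is essential at junctions, where the read carries a *chimeric*
  element — two halves of different copies, possibly opposite
  orientations — that a full-length consensus alignment misses. A
  shared-k-mer screen skips reads that cannot contain the element.
* **Flank mapping (builtin):** unique reference 15-mers anchor each
  flank; anchors are chained per (chromosome, strand, diagonal band) and
  the best chain per flank is reported, with identity estimated as
  anchor-density^(1/k) (the per-base accuracy implied by exact-k-mer
  survival). The mapper is intentionally minimal: on repetitive flanks
  or real genomes, split alignments are imported from PAF instead, and a
  test verifies that builtin and minimap2-PAF routes produce the same
  call set on error-free reads.
* **Calling:** a read votes when its element interval has ≥ 200 bp
  mapped flanks on both sides that abut the element in read coordinates
  (within 150 bp — a chain that stops short, e.g. at a second junction
  inside the flank, does not localise this junction) and the two flanks
  map to different chromosomes, > 100 kb apart, or with inconsistent
  strands. "Different chromosomal parts" has no canonical threshold;
  100 kb safely exceeds any intact element locus. Votes are clustered
  within ±500 bp on both ends; support accumulates.
* **Evaluation:** greedy 1–1 matching to truth junctions, both ends
  within ±500 bp, ends unordered.

A structural limitation is inherited from the flank-based approach: the
called breakpoints sit at the element-proximal flank ends, i.e. at
element boundaries, while the true cut lies inside the element. For
~300 bp Alu-like elements the offset is below the ±500 bp tolerance; for
6 kb L1-like elements it can reach kilobases, so the default evaluation
scene anchors on the short-element family. On that scene (10 Mb, ~30
junctions, 15x depth, 8 kb mean reads) the caller attains precision =
recall = 1.0 on inter-chromosomal junctions with error-free reads, and
recall ≥ 0.9 / precision ≥ 0.95 at 5% uniform error.

## Read simulation

Long-read lengths follow a gamma distribution (shape 2) with
configurable mean (default 8 kb), truncated below at 500 bp; start
positions are uniform over the derivative genome. Errors are applied as
60% substitutions / 20% insertions / 20% deletions of the total rate —
a generic long-read error mix, not a machine-specific model. Each read
records its exact origin as source-coordinate intervals through the
derivative segment map; reconstructing an error-free read from its
origin reproduces the read exactly (property-tested).

## What the synthetic data does and does not show

The generator emulates: repeat-seeded multi-site cleavage, NHEJ-style
reassembly with intra-chromosomal preference, segment gain/loss,
depth-proportional binned counts, and junction-spanning noisy long
reads. It does not emulate: truncated/nested repeat copies, sequencing-
machine error profiles, diploid/triploid genotypes, selection among
surviving cells, or chromatin-contact-informed rejoining. Passing tests
therefore demonstrate correctness of the computations under the model's
assumptions, not performance on real sequencing data — with the partial
exception of the PAF import route, which lets the caller consume real
aligner output.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` with explicit
  per-stage seeds derived from one base seed (all below 2^31); every
  generator and the full pipeline report are byte-reproducible.
* Bins are half-open, anchored at coordinate 0; the last bin may be
  short and is kept (its truth is an exact base sum, so no edge bias).
* Strict exceedance in the quantile rule makes a flat profile yield no
  regions; a zero-variance profile likewise yields none under the
  z rule.
* Chi-square expected counts are rescaled to the observed total when the
  null is simulated at a different event count (calibration use only).
* Degenerate statistics (no junctions, zero variance) report p = 1 with
  an explicit flag rather than raising.
* Problem sizes in the validation experiments (1 Mb oracle genomes,
  10 Mb scenes, 500 permutation-calibration replicates, 15x long-read
  depth) are chosen so the whole suite runs in minutes on a single CPU
  while keeping every statistic in its asymptotic regime.

## Known limitations

* Junction classification of deletions vs intra-chromosomal
  translocations is heuristic when segments move (it checks whether the
  skipped interval was actually lost); the inter/intra dichotomy used by
  the statistics is exact.
* The builtin flank mapper requires unique k-mer anchors and will not
  chain through long perfect repeats; that regime is delegated to PAF
  import from a real aligner.
* Guide-site enumeration is exhaustive Hamming matching (no bulges, no
  CFD/MIT scoring) and is not tuned for 3 Gb genomes, though nothing in
  it is scale-limited except memory-linear scan time.
* The breakpoint-position convention for long-element-anchored calls
  (element boundary, not cut site) is documented above.
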