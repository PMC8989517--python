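# gcrtools

Simulation and analysis of **global chromosome rearrangement (GCR)** —
the genome state produced when CRISPR–Cas9 is directed at a highly
repetitive target (conserved regions of LINE-1 or Alu retrotransposons),
creating many simultaneous double-strand breaks that are rejoined by
non-homologous end joining (NHEJ) into translocations, inversions and
copy-number changes.

The package is for computational biologists who want to develop or
validate rearrangement analyses against a fully known ground truth. It
pairs a simulator — synthetic genomes with embedded repeat copies
carrying guide matches, multi-site cleavage and stochastic NHEJ-style
reassembly — with the analyses used to characterise rearranged genomes:

* **guide search** — every genomic match of a 20-nt guide with ≤ 2
  mismatches on both strands (optional NGG PAM), exhaustive
  report-all-alignments semantics;
* **cut-and-rejoin simulation** — derivative chromosomes plus exact
  junction and copy-number truth;
* **CNV analysis** — per-bin normalized count differencing against a
  control, high-CNV region calling, base-pair region intersection,
  per-bin and per-chromosome correlation, interval coverage ratios;
* **breakpoint statistics** — permutation (shuffle) enrichment of
  breakpoints in region sets with normal-approximation and empirical
  one-sided P; a Monte-Carlo intra- vs inter-chromosomal null with
  chi-square test and the closed form Σᵢ(Lᵢ/L)²; breakpoint-to-nearest-
  repeat distances; 2-D genome linearization for breakpoint plots;
* **long-read SV calling** — reads containing a repeat element are
  found by tiled edit-distance alignment, their flanks split-mapped
  (builtin unique-k-mer chainer or imported PAF), and a translocation is
  called when the flanks map to different chromosomal parts; calls are
  clustered across reads and evaluated against truth.

The core statistics, in the field's notation: the permutation test
reports z = (T_obs − ½ − μ̂)/σ̂ (continuity-corrected, T being a count)
and p = 1 − Φ(z) for the number T of breakpoints in length-preserved
uniformly re-placed regions, plus the exact empirical permutation P; the MC null
draws endpoint pairs uniformly (chromosome ∝ length), giving intra
fraction Σᵢ(Lᵢ/L)² in closed form, tested against observed counts by
chi-square (1 df); CNV values are normalized_count(GCR) −
normalized_count(control) per bin.

## Worked example

Run the full synthetic experiment (three arms: sgL1, sgAlu and the
no-match negative control sgNC) at a small demo scale:

```python
import gcrtools as g

cfg = g.RunConfig(n_chromosomes=3, chrom_length=300_000,
                  l1_copies=10, alu_copies=50, bin_size=20_000,
                  n_permutations=200, cut_probability=0.6,
                  longread_coverage=3.0, seed=7)
cfg.to_yaml("demo_config.yaml")
```

```bash
gcrtools run-all --config demo_config.yaml --out demo_run
```

prints (sd/means abbreviated):

```
{"sgAlu": {"cnv_profile_sd": 19.19, "n_cuts": 23, "n_junctions": 23, "n_matches": 30, ...},
 "sgL1":  {"cnv_profile_sd": 23.24, "n_cuts": 5,  "n_junctions": 6,  "n_matches": 6, ...},
 "sgNC":  {"cnv_profile_sd": 12.60, "n_cuts": 0,  "n_junctions": 0,  "n_matches": 0, ...}}
```

Reading it: the Alu-targeting guide has 30 matching sites in this 900 kb
genome versus 6 for the L1 guide (mirroring the real >40-fold gap in
site counts), so its arm accumulates more cuts and junctions; the
negative control matches nowhere and stays untouched — its per-bin CNV
profile is pure Poisson differencing noise around zero (sd ≈ 12.6 at
depth 100 per bin after library-size normalization). `demo_run/report.json` carries the full statistics, e.g.
for the sgAlu arm:

* Monte-Carlo intra/inter null: observed 7 intra / 16 inter junctions
  vs expected 8.4 / 14.6 under the uniform null (closed form 1/3 for
  three equal chromosomes), chi-square p = 0.54 — at this small scale
  and weak distance kernel the intra preference is not significant;
* nearest-element distances: all 46 breakpoint ends lie inside an
  Alu-like element, as they must when every cut happens at a guide site;
* long-read calling at 3x depth: 13 inter-chromosomal calls from 153
  element-containing reads, precision 1.0, recall 0.81 against the 16
  true inter junctions (recall reaches 1.0 at the default 15x depth).

Per-arm standard-format outputs (`junctions.bedpe`, `cnv_profile.tsv`,
`high_cnv_regions.bed`, `segments.tsv`, `copy_truth.tsv`, plus
`genome.fasta` and `repeats.bed`) are written next to the report, all
re-readable by `gcrtools.formats`. Individual stages are available as
subcommands: `simulate-genome`, `guide-search`, `simulate-gcr`,
`simulate-reads`, `cnv`, `breakpoint-stats`, `longread-sv`.

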