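# Methods

## Model and procedure

`zparcall` identifies avian Z-linked sequence and the pseudoautosomal
region (PAR) from two signals available for any draft assembly with
resequencing data from the assembled individual:

* **Copy number via depth.** Let `D_w` be the mean per-base depth of a 5 Kb
  window and `D*` the modal window depth genome-wide. Normalized depth
  `d̂_w = D_w / D*` estimates copy number / 2. Expected values per region
  class and sex (the generator's copy factors, also the classifier's
  reading of the data):

  | class   | male | female |
  |---------|------|--------|
  | autosome| 1.0  | 1.0    |
  | Z PAR   | 1.0  | 1.0    |
  | Z DR    | 1.0  | 0.5    |
  | W       | 0.0  | 0.5    |

* **Homology via whole-genome alignment.** Scaffolds whose merged
  (interval-union) aligned fraction against a reference Z exceeds 0.5
  (strict inequality) are Z candidates. This leans on the strong
  conservation of the avian Z; W-derived scaffolds align poorly and fall
  into NOT_Z — the pipeline deliberately does not call W.

Sex is inferred from the modal `d̂` of Z-candidate windows: female if in
[0.3, 0.7], male if ≥ 0.85, otherwise UNDETERMINED. The bands are wide
because the two hypotheses sit at 0.5 and 1.0 with typical mode noise well
under 0.05; an explicit UNDETERMINED outcome surfaces mislabeled or
contaminated samples instead of forcing a call. PAR calling requires a
female sample, since only the heterogametic sex shows the PAR/DR contrast.

PAR calls are made at two levels: per scaffold (median `d̂` over full
windows strictly above 0.7; the median resists repeat-driven depth spikes)
and per window along the pseudo-Z (runs of windows with `d̂ > 0.7`,
labeled PAR, remainder DR). The pseudo-Z is built by sorting Z candidates
by anchor position (median of alignment-block midpoints on the reference —
robust to minor chimeric blocks), orienting each by aligned-base-weighted
strand majority (exact ties default to `+`), and concatenating with fixed
100 bp gaps; unanchorable candidates are appended at the end and flagged
so total Z length is conserved. A total PAR length strictly above 5 Mb
raises the reversal flag: an order of magnitude above the conserved
~600 Kb avian PAR and an order below the ~30 Mb anomaly that motivates the
detector, and configurable.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| window_size | 5000 | bp | depth aggregation window |
| rate_threshold | 0.5 | fraction | Z candidacy, strict `>` |
| par_depth_threshold | 0.7 | normalized depth | PAR, strict `>` |
| min_run / max_gap | 3 / 2 | windows | segmentation hysteresis |
| reversal_min_length | 5,000,000 | bp | reversal flag, strict `>` |
| gap_size | 100 | bp | pseudo-Z inter-scaffold gap |
| track_resolution | 100,000 | bp | binned PAR/DR/GAP track |
| peak bin width | median/50 (≥1) raw; 0.02 normalized | depth | histogram bins |

The segmentation hysteresis absorbs up to `max_gap` consecutive
sub-threshold windows inside a PAR run and discards runs shorter than
`min_run` windows; at the default noise level (~10 % CV per window) a
lone mis-thresholded window is a ≳3σ event, so isolated flips are
suppressed while true boundaries move by at most about one window.

## Numerical choices

* **Peak (mode) estimation.** Histogram argmax with bins centered on
  multiples of the bin width, ties to the lower bin, partial terminal
  windows excluded, then **three-point parabolic sub-bin refinement**
  around the modal bin. The refinement matters: at 30× the integer raw
  bins would otherwise quantize the normalization scale by ~3 %, and on
  the flat-topped normalized histogram a plain argmax wobbles by 1–2 bins;
  the parabola vertex is stable to well under half a bin. `refine=False`
  restores the plain bin-center estimator.
* **Coordinates.** Everything in memory and in BED/PAF/placement output is
  0-based half-open; per-base depth input is 1-based (samtools dialect)
  and AGP output 1-based inclusive, with conversions confined to the
  readers/writers. Reverse-oriented placement reflects intervals within
  the scaffold (`end' = L − start`), a bijection on bases.
* **Thresholds are strict inequalities** (>0.5 aligned, >0.7 depth,
  >5 Mb reversal); boundary values are excluded everywhere, and tests pin
  this.
* **Degenerate inputs.** Fewer than 100 full windows → peak estimation
  refuses; no Z candidates → sex inference refuses; PAR calling on a
  non-female call refuses with an explanation; empty segment/gene tables
  yield zero counts, not errors.
* **Determinism.** Every stochastic stage takes an explicit seed derived
  from the single configuration seed; identical configurations produce
  byte-identical output files (fixed float formatting).

## The synthetic-data generator

The generator emulates the measurement process, not the reads:

* **Karyotype.** Region classes AUTOSOME / Z_PAR / Z_DR / W tile each
  chromosome. The `typical` preset encodes the conserved layout —
  75,476,763 bp Z with a 610,563 bp PAR holding 11 of 585 Z genes — and
  the `reversal` preset the anomalous one — 74,940,613 bp Z whose first
  29,966,716 bp behave pseudoautosomally with 228 of 602 genes. Both add
  a 200 Mb autosomal complement (four macro-chromosomes standing in for a
  ~1.1 Gb genome at desk scale), a 7 Mb W complement, 30× autosomal
  depth, and a female sample.
* **Fragmentation.** Chromosomes are cut at Poisson-process breakpoints
  (exponential spacing, mean 2 Mb by default — draft-assembly scale);
  length is conserved exactly and each scaffold records its source
  interval and per-class base composition.
* **Depth.** Window depth sums are gamma-Poisson (negative binomial):
  `λ ~ Gamma(k, m/k)`, `S ~ Poisson(λ·span)`, `D = S/span`, with `m` the
  class×sex mean and `k = 100` the dispersion (≈10 % CV on 5 Kb window
  means at 30×, a realistic overdispersion for short-read resequencing;
  `k → ∞` recovers the Poisson limit). A window's expected depth follows
  the majority class of its footprint.
* **Alignments.** Z-derived scaffolds get PAF blocks at their true source
  coordinates covering Beta-distributed fractions around 0.9; other
  scaffolds get sparse spurious blocks covering at most 0.05. Each
  scaffold's strand is drawn at random and kept as truth.
* **Genes.** Exact per-class counts of 20 kb genes placed uniformly and
  non-overlapping within each region (sorted-uniform spacing
  construction), then lifted to scaffold coordinates (majority-scaffold
  assignment with clipping at breakpoints).

**What passing on synthetic data does and does not show.** The generator
reproduces copy-number depth structure, assembly fragmentation, alignment
coverage contrast and annotation geometry, so it validates the inference
logic, thresholds, coordinate bookkeeping and file interfaces end to end.
It does **not** model mappability variation, repeat-driven depth spikes,
GC bias, chimeric scaffolds, W-homologous (gametologous) sequence aligning
to the Z, or assembly gaps — so real-data performance near repeats and on
a degraded W is not certified by these tests.

## Problem sizes

The packaged presets simulate ~282 Mb of genome (~56,500 windows of 5 Kb,
~150 scaffolds), chosen as the smallest configuration that preserves the
published Z/PAR geometry at full resolution while a complete pipeline run
takes ~1 s on one CPU; the validation suite runs 43 such replicates.

## Known limitations

* The PAR boundary is resolved to window granularity (5 Kb); sub-window
  boundaries are rounded toward the PAR interior.
* Reference-guided ordering assumes large-scale Z synteny; true
  rearrangements relative to the reference Z reorder the pseudo-Z rather
  than being detected.
* The reversal detector flags total PAR length only; it does not test
  depth-ratio significance or date the event.
* RBH orthology ignores synteny and paralogy; with duplicated genes the
  one-to-one table keeps whichever copy wins the reciprocal criterion.
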