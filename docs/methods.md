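# Methods

This note documents the models, numerical choices and open design decisions
behind `chromatlas`, and what the synthetic-world tests do and do not
establish about real data.

## Coordinate and interval conventions

Everything internal is 0-based half-open (BED). GTF input (1-based,
inclusive) is converted on read. Sorting is by (chromosome lexicographic,
start, end, name) so outputs are reproducible byte-for-byte. Overlap always
means ≥ 1 bp unless a `min_bp` argument says otherwise; book-ended
intervals ([0,10) vs [10,20)) therefore do **not** overlap for counting
purposes, but **are** merged by `merge_intervals` at `max_gap = 0`, matching
the defaults of the corresponding bedtools operations (`intersect`,
`merge`). `intersect_regions` returns one overlap *segment* per overlapping
pair — the consensus-construction semantics — while whole-peak selection is
`count_overlapping`. The test suite cross-checks both operations against
the bedtools binary and against per-base boolean-array oracles.

`shuffle_set` relocates each interval width-preservingly: chromosome drawn
with probability proportional to length, start uniform on the feasible
range, redrawn (up to 1 000 attempts) while the placement overlaps the
exclusion mask. Placements are drawn in vectorized rounds from a single
seeded generator, so results are deterministic given the seed.

## Library QC statistics

- `%informative = 100·I/R` and `NRF = (M−D)/M` are reported at two decimals,
  the precision used in the bundled published tables; the package reproduces
  all 31 published values exactly from the raw counts.
- FRiP counts a fragment as "in peaks" on ≥ 1 bp overlap.
- Binned coverage tiles each chromosome with fixed windows (default 500 bp,
  last window truncated); a fragment increments every window it touches.
  RPM/RPKM scalings are available for export and plotting; Pearson
  correlation is scale-invariant so replicate correlation uses raw counts.

### sJSD: a declared reimplementation

The synthetic Jensen–Shannon distance is defined here as
`sqrt(JSD₂(P, Q))` where `P` is the normalized histogram of per-window
fragment counts and `Q` the histogram of an i.i.d. Poisson sample with the
same number of windows and matched mean, drawn from the given seed. The
value is symmetric, bounded in [0,1], zero on self-comparison, and grows as
coverage concentrates. Fingerprint-style tools derive an equivalent-spirit
statistic from coverage curves; bit-level agreement with any external tool
is explicitly not promised, and no test asserts it.

## Consensus atlas

Reproducible regions per tissue are `merge(intersect(repA, repB))`. The
choice of *segments* rather than whole peaks is deliberate: it keeps the
consensus conservative (only bases supported by both replicates) and is one
of the two readings of the published procedure; published per-tissue widths
are compatible with either. If exact reproduction of published counts is
attempted (see the red acceptance test), segment-vs-whole-peak sensitivity
should be the first thing examined. Single-replicate tissues accept a
stringent externally provided peak set and pass it through merged — the
pipeline does not re-call peaks.

The tissue-specific rule is strict by design: a consensus peak accessible in
tissue *t* is disqualified by ≥ 1 bp overlap with *any* raw replicate peak
of *any* other tissue, including sub-reproducible single-replicate calls.
Consequently tissue-specific ⇒ activity k = 1, but not conversely; tests
assert only that implication direction.

## Feature categorization and the enrichment null

Categories are assigned by first-overlap precedence (TSS, promoter, TTS,
5′UTR, 3′UTR, CDS, intron, intergenic), which makes the counts a partition.
Numerical choices:

- TSS/TTS zones are ±50 bp *inclusive* (101 bp).
- The promoter is the 2 kb strictly upstream of the TSS, strand-aware; the
  conservation stratification extends it to (TSS−2000, TSS+50).
- The exonic category uses coding-sequence intervals (CDS), the more
  specific of the two plausible readings of "exonic".
- Genes are collapsed to one 5′-most TSS and 3′-most TTS; introns are the
  gene span minus exons.
- The enrichment test compares raw counts, not proportions (equivalent up
  to scaling at fixed peak number).
- The unmappable mask is empirical: 500 bp tiling windows with zero
  fragment overlap in every library, merged.

### Two p-values

The classical randomization summary compares the observed count `x` with
`n = 100` shuffled counts via a one-sample t-test,
`t = (x̄ − x)/(s/√n)`. This statistic scales with √n: under the null the
variance of `x̄ − x` is `s²(1 + 1/n)`, dominated by the observation's own
variance, so treating `x` as a fixed hypothesized mean inflates |t| by
roughly √n and the nominal α = 0.05 test rejects a true null ~40 % of the
time. `EnrichmentResult` therefore carries both:

- `p` — the √n-scaled one-sample form, kept as the primary reported value
  for continuity with common practice (its *direction* is what matters for
  the strong enrichments the pipeline flags, e.g. planted-TSS p ≪ 1e-100);
- `p_calibrated` — denominator `s·√(1 + 1/n)`, the predictive-interval
  form, exactly t-distributed for a normal null and approximately uniform
  here. The calibration property test (empirical type-I error in
  [0.03, 0.07] at α = 0.05 over 500 simulation seeds) is asserted on
  `p_calibrated` for the best-populated category (intergenic), where the
  normal approximation to the count distribution is adequate; sparse
  categories (TTS, UTRs) are visibly lumpy at 40 peaks and are not held to
  the band. A companion assertion documents the anticonservativeness of
  `p` (rejection rate > 0.2 under the null).

Degenerate nulls (`s = 0`) are flagged; p is 0, 1 or 0.5 by the sign of
`x̄ − x`.

## Cross-species projection and conservation

A homology map abstracts a whole-genome alignment into equal-width directed
blocks with orientation; source blocks within one map must be
non-overlapping. Projection transfers each overlapping sub-interval
linearly (reversed for "−" blocks), groups images by (target chromosome,
orientation), and merges groups whose gap is ≤ `group_gap` (default
10 kb). The multi-locus criterion — ≥ 2 groups after merging — is a
package decision (the grouping gap is an exposed parameter), since no
standard definition exists for when a projection counts as "multiple loci".

Conservation modes: `any_tissue` (both sides accessible somewhere) and
`same_tissue` (≥ 1 tissue accessible on both sides after alias
translation). Shared tissues are reported in the *source* species'
vocabulary so multi-target intersections (three-way analysis) compare like
with like. Three-way sets are anchored on an explicit reference species;
pairwise conservation is not assumed symmetric, and the tests assert only
the monotone filtration conserved ⊆ uniquely-mappable ⊆ consensus and
same_tissue ⊆ any_tissue.

## The synthetic world

The generator emulates the structure of a multi-tissue, two-replicate,
three-species ATAC-seq study with every measurable quantity governed by an
explicit knob. Defaults (the standard study conditions):

| knob | default | controls |
|---|---|---|
| genome | 3 species × 2 chromosomes × 5 Mb | problem size |
| genes | 200/species on a 20 kb grid | annotation density |
| planted peaks | 120 housekeeping-TSS (all tissues), 80 tissue-specific × 8 tissues, 400 shared (2–7 tissues) | atlas composition |
| peak width | lognormal, median 500 bp, σ = 0.45, clipped [150, 1200] | published width scale |
| replicate detection d | 0.8 | replicate overlap |
| boundary jitter | ±10 % of width | peak-call variability |
| noise peaks | Poisson(150)/library, confined to a 1 Mb noise zone | irreproducible calls |
| fragments/library | 50 000; in-peak fraction f = 0.35 | FRiP ≈ 35 % (published mean 34.8) |
| duplication u | 0.6 (one extra copy w.p. u) | NRF = 1/(1+u) ≈ 0.625 (published mean 0.62) |
| sequence conservation | promoter 0.8 / distal 0.5 (near pair), ×0.6 far pair | mappable fractions |
| accessibility conservation given sequence | promoter 0.625 / distal 0.3 | conserved fractions 0.50 / 0.15, the promoter-vs-enhancer contrast |
| activity shuffle | 0.25 of acc-conserved distal partners | same-tissue < any-tissue gap |

Layout decisions that make truth bookkeeping exact: each chromosome has a
gene region, a distal-slot grid and a separate noise zone, so noise can
never collide with planted loci; homologous loci share a slot index across
species, and homology blocks are emitted at peak-locus granularity (peak ±
300 bp flank), so projections are unique by construction and the projection
truth is exact. Private peaks in the non-reference species avoid every
reference housekeeping slot so a sequence-conserved but not
accessibility-conserved projection can never be scored conserved by
accident. Background fragments are placed strictly outside the library's
peaks (complement sampling with a width margin), making FRiP an exact
binomial in f. The third species carries a mouse-style panel: no
hypothalamus, adipose→mesenteric_fat and cortex→cerebrum renames, exercised
through the tissue-alias table.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence content and mappability structure, Tn5
insertion bias, fragment-length nucleosome laddering, peak-width/intensity
correlation, annotation incompleteness, and genuinely shared noise between
replicates. Replicate binned-signal correlation in the synthetic world is
therefore well below the ~0.97 of deep real libraries.

Parameter recovery (`recover_parameters`) compares pipeline measurements
with expectations: binomial 3-standard-error bands for stochastic rates
(FRiP, NRF), exact truth-bookkeeping for replicate overlap and
tissue-specific counts in noise-free worlds, and both truth-derived and
configured-rate comparisons for stratified conservation (the configured
0.50/0.15 contrast is recovered under certain detection d = 1, where
partner reproducibility cannot attenuate it).

## Problem sizes used in the checked runs

The test suite and the acceptance script run reduced worlds (100–200 genes,
~300–700 planted peaks, 2 000–20 000 fragments per library) chosen so the
binomial tolerances stay meaningful while the whole suite completes in
about half a minute; the calibration study uses 500 simulation seeds ×
100 shuffle iterations on a 40-peak, 200 kb toy genome. These are the
package's own desk-scale study conditions; the full defaults above generate
in a few seconds and are exercised end-to-end by the examples.

## Known limitations

- The consensus-segment vs whole-peak ambiguity (above) is unresolved
  against the published counts without the journal supplement.
- `sJSD` is a reimplementation, not a clone of any fingerprint tool.
- The enrichment `p` is anticonservative by construction (kept for
  continuity); use `p_calibrated` when calibration matters.
- Homology maps assume non-overlapping source blocks (one best alignment
  per locus); paralogous tilings must be pre-resolved upstream.
- The CLI's world-directory layout is a convention, not a registry; real
  data must be arranged into it (or the library API used directly).
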