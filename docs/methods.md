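# Methods

This note documents the models, parameter choices and numerical decisions
behind `teepi`, and what the synthetic cohort does and does not emulate.

## Coordinate and signal conventions

All coordinates are 0-based half-open (BED convention) internally; GFF input
is converted on read.  Signal tracks are fold-enrichment values averaged
into fixed 10 bp bins; a bin's value is the coverage-weighted mean of the
bedGraph intervals overlapping it.  Missing signal is NaN, never 0 —
assembly gaps and contig edges must not masquerade as depletion.  A window
with more than 50 % missing bins (configurable, `max_missing_fraction`) is
excluded from testing; the treatment of contig-edge windows is our choice,
as is everything else in this paragraph below the bin size.

TE strand is ignored for window geometry: "left" and "right" are
reference-orientation flanks.  Carrier windows anchor at the TE's outer
edges and non-carrier windows at the single projected breakpoint — the only
geometry under which TE+/TE− windows cover homologous sequence with the TE
body excluded.

## Breakpoint projection

"Unique mapping" is operationalized as exactly one primary alignment with
mapping quality ≥ 30 covering ≥ 80 % of the flank; secondary alignments are
ignored.  When the gap/overlap g between the projected flanks is non-zero
(|g| ≤ 50 bp tolerated), the junction is placed at the midpoint rounded
toward the upstream side — any point inside the tolerance interval would be
defensible.  Widening the tolerance can only convert non-unique calls to
unique, never the reverse (tested).  For synthetic genomes a built-in
exact-substring mapper produces the same record format as a PAF alignment
file, so the caller logic is identical for both input routes; real data
flows in as PAF from an external aligner.

## Window statistics

The Wilcoxon rank-sum sample units are the replicate-averaged 10 bp bin
values within a window (~100 per genome per window).  This choice gives the
test within-window replication; per-window replicate means would leave n = 3
per group.  Small tie-free samples use the exact null distribution;
otherwise the tie-corrected normal approximation with continuity correction
is used (the batched implementation and the scalar path agree to float
precision; both are validated against full enumeration for group sizes ≤ 8).
Tests are two-sided with post-hoc direction from the median difference.  No
multiple-testing correction is applied across windows; `alpha` (default
0.05) is configurable.

The percentage change pools the bins of both innermost windows before
taking medians (a per-side variant would be straightforward but the pooled
form is the default).  The spread requires window 1 significant on *both*
sides; a TE significant on only one side is "none".  A pair whose rank-test
direction contradicts the sign of the pooled median percentage — possible
only in borderline noise — is treated as NA rather than reported with an
inconsistent sign.

Consensus across the carrier × non-carrier pair grid keeps the modal
non-NA class when at most one pair deviates (by class or NA) and excludes
the TE otherwise; reported P and S are means over the concordant pairs
(the aggregation across pairs is our choice).  "Bivalent" means both marks
changed in the same direction within one body part, "mix" opposite
directions within one body part; opposite effects across body parts remain
reportable per body part.

## Metaprofiles

Per-offset medians across TEs (left flank reversed so offsets run −20 kb …
+20 kb, TE body excluded) are smoothed with degree-1 LOWESS, tricube
weights, span 10 % of offsets, no robustness iterations (statsmodels
`lowess`).  The x-axis is distance from the TE edge, not the midpoint.

## Expression linkage

TMM normalization follows the published trimmed-mean-of-M-values scheme:
reference sample = 75th-percentile-of-relative-counts closest to the mean;
per sample, log2 ratios M and average abundances A over genes positive in
both members; 30 % of M and 5 % of A trimmed from each tail by rank;
weights = inverse delta-method variance; factors rescaled to unit geometric
mean.  The implementation reproduces an independently coded reference and
Bioconductor edgeR's `calcNormFactors` to ≤ 1e−8 on random negative-binomial
matrices.  Normalized abundance is CPM over the TMM-effective library size.

The z statistic uses the Welch-style combined standard error
√(SE₊² + SE₋²); the significance cutoff |z| ≥ 1.96 and the expressed-gene
filter (mean normalized abundance ≥ 1 in the body part) are configurable
defaults.  Replicates of all carrier strains are pooled against all
non-carrier replicates by default; a per-strain-average-first mode exists
(`average_replicates_first`) because the grouping is a genuine modelling
choice.  Degenerate cases: both groups constant and equal → z = 0; zero
combined variance with unequal means → signed infinity, flagged significant.

Positional categories relative to a gene model use overlap precedence
CDS > 5′UTR > 3′UTR > intron, with upstream/downstream assigned in the
gene's reading orientation; genes without sub-feature structure get
distance-only categories and are flagged.

## Null models

The permutation statistic is not uniquely determined by the design, so it
is configurable: the default for the positional test is the proportion of a
TE set's gene links significantly downregulated (z ≤ −1.96); a continuous
mean-z variant exists and is what the uniformity validation uses, because
a heavily tied discrete statistic makes the add-one p conservative rather
than uniform.  Null TE sets preserve the focal set's positional-category
histogram exactly, drawn without replacement within a draw and
independently across draws.  Empirical p = (1 + #{null ≥ obs}) / (N + 1),
never 0, equal to 1/(N+1) when the observation beats every draw.

TE-free control regions are sampled uniformly (rejection sampling with an
attempt cap and an explicit shortfall report) with no TE within 1 kb,
length matched to the TE they control for, and positional category matched
relative to the nearest gene within 1 kb ("intergenic" beyond that).

## Family tests

Families need ≥ 20 genomic copies and ≥ 8 affected copies to be tested.
The test is a one-sample χ² goodness-of-fit against the cohort-wide effect
proportion (recomputed from the input, never hard-coded); when an expected
cell falls below 1 the exact binomial test substitutes, flagged in the
output.  Raw p-values are reported to match the original analysis; a BH
column is emitted alongside.  The generic 2×2 utilities use the Yates
continuity correction (χ²) and the "sum of probabilities ≤ observed"
convention for the two-sided Fisher test, validated against hypergeometric
enumeration.

## Synthetic cohort

The generator emulates the study design: 5 strains, 3 body parts, 2 marks,
3 ChIP replicates, polymorphic TEs (1–4 carriers of 5), with defaults of
200 TEs, lognormal fold-enrichment noise with log-sd 0.2 around median 1,
and a planted enrichment of +50 % spreading 3 kb on a random half of the
TEs, each effect planted in one randomly chosen body part × mark.  The
effect kernel is a boxcar (constant multiplier, hard edge) so the spread
estimator has an unambiguous true value.  Expression is negative-binomial
(dispersion 0.1, lognormal baseline means) with linked genes shifted by
|log2FC| = 1 in carrier samples of the affected body part, signed
concordantly with the mark (repressive enrichment → down, active
enrichment → up).

Geometry: one base chromosome of uniform-random nucleotides shared by all
strains; each strain's genome splices in the TE sequences it carries, drawn
from a small synthetic family library (independent random sequences, hence
≥ 20 % mutual divergence), so per-strain coordinates differ by cumulative
insertion lengths and every non-carrier junction is known exactly.  TEs are
spaced ≥ 2 × the analysed span apart ("isolated" placement) so windows
never overlap a neighbouring insertion.

What the generator does **not** emulate: spatially decaying effect kernels,
correlated noise along the chromosome or between strains, piRNA-cluster
biology, nested or heterochromatic insertions, mappability artefacts, and
read-level sampling.  Passing the planted-truth tests therefore
demonstrates the correctness of the inference machinery under the stated
noise model, not performance on real ChIP data, where effect shapes and
noise are less benign.

## Problem sizes and validation surfaces

The planted-truth and null-calibration checks run a 200-TE, 5-strain,
3-replicate cohort with the full ±20 kb window geometry (1,200 TE × body
part × mark combinations, ~6,000 strain pairs, ~240,000 window tests);
these complete in well under a minute each.  The consensus caller is scored
against the generator's truth with the projected-junction step validated
separately on a sequence-bearing cohort (100 TEs, all junctions recovered
exactly; a 60 bp insertion planted at a junction is rejected by the ±50 bp
rule).  Permutation uniformity uses 200 repetitions of N = 1000 draws.

## Known limitations

* The exact-substring mapper is intended for synthetic genomes only; real
  flank alignment must come from an external aligner via PAF.
* Windows are fixed at 1 kb; sub-kilobase effects dilute into window 1 and
  shorten the estimated spread.
* The consensus "at most one deviating pair" rule is insensitive to cohort
  size: with many strains a stricter fraction-based rule may be preferable.
* Interval queries use linear scans; cohorts far beyond ~10⁴ TEs × genes
  would warrant an interval index.
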