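# Methods

This note documents the models, conventions and numerical choices behind
`matekin`, and what the synthetic-data tests do and do not establish about
real cohorts.

## Identity and relatedness

Genotypes are unordered biallelic calls; internally each call is the dosage
of the SNP's second allele (0/1/2, −1 missing), which makes the per-SNP
identity score pure arithmetic: `1 − |d_a − d_b|/2`, overridden by the
het–het score *s* when both calls are heterozygous.  Phasing is never used:
identity is scored per genotype in all modes.  Multi-allelic or indel
variants are rejected at parse time; the panel model is strictly biallelic.

Q for a pair is the mean score over SNPs where both calls are present
(pairwise-complete; the per-pair SNP count is kept for QC).  A pair with no
usable SNP is an explicit undefined state (NaN plus `undefined_pairs()`),
never silently zero.  The all-pairs computation is a handful of one-hot
matrix products, exact in double precision; a brute-force allele-by-allele
matcher serves as the independent oracle in the test suite.  The matrix
diagonal is computed only on request (`self_identity`): with *s* = 0.5 a
heterozygous individual scores below 1 against itself, which is the
diagnostic motivating the *s* = 1 variant.

Relatedness is the affine transform R = (Q − Q̄)/(1 − Q̄), with Q̄ the mean
over all unordered pairs of cohort members — both sexes, diagonal excluded,
known relative pairs excludable.  R is strictly increasing in Q, so it
preserves ranks; Q̄ < 1 is enforced.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `het_het_score` | 1.0 | credit for het–het comparisons; 0.5 reproduces the older convention, any value in [0,1] is accepted |
| MAF floor | 0.01 | SNPs below this minor-allele frequency are dropped; MAF can be computed on all samples (default) or parents only, before (default) or after couple exclusions |
| relative threshold | 0.2 | pairs with R at or above it are flagged as close relatives; first-degree pairs sit near 0.5, so 0.2 splits them cleanly from the null spread (±~0.05 at 2,000 SNPs) |
| `n_trials` | 100,000 | random pairings per test; the empirical-P standard error √(α(1−α)/n) is ~14% of α at 1,000 trials and ten-fold smaller at 100,000 |

Coordinates are 1-based with region endpoints inclusive on both ends;
chromosome labels are normalized by stripping a `chr` prefix; the missing
genotype token is `NN` (any token containing `N` is missing, any other
token outside the SNP's allele pair is an error).  No coordinate lift-over
is performed: regions must be supplied on the panel's build.

## The mate test

The observed statistic is the mean (or median, for the robustness variant)
R over real couples.  Each trial pairs the male set with a uniformly random
permutation of the female set; two-sided P counts trials with |statistic| ≥
|observed|, one-tailed variants count ≤ or ≥, and ties always count (no
randomized tie-breaking).  Real couples are allowed in trials by default;
disabling them redraws identity permutations.  The Z score divides the
mate/non-mate location difference by the non-mate standard deviation with
the sample (n−1) denominator.  One-tailed directions are configuration,
fixed before the run.  For the median variant the location is the median on
both sides while the scale remains the non-mate SD, keeping Z comparable
across variants.

Exclusion permutations: a flagged relative pair is resolved by removing any
couple containing either member (couples, not individuals, are excluded; a
related mate pair forces its own couple out).  All minimal hitting sets on
the conflict structure are enumerated exactly (branch-and-bound with a
minimality filter, capped at 64 by default — exceeding the cap signals the
threshold needs review, not a bigger cap).  k disjoint cross-couple
conflicts yield exactly 2^k permutations.  Aggregate P and Z are the
arithmetic means across permutations; the per-permutation table and the
min–max ranges are always retained, since the spread between permutations
is itself a robustness diagnostic.  RNG streams are derived per permutation
from one root seed, so results are reproducible and independent of
evaluation order.

Leave-one-out reruns the test dropping each couple in turn (baseline
recomputed without the dropped members) and ranks couples by their
full-cohort mate R — the standard probe for results carried by one extreme
couple.

## Segment scan

Segments of 3.6 Mbp are tiled every 300 kbp from position 1.  A segment is
excluded when truncated at the chromosome end (the fixed-length
recombination denominator presumes full segments), overlapping a centromere
or the query locus (closed-interval overlap, one shared basepair
suffices), holding fewer than `min_snps` SNPs (default 1000), or lacking
two genetic-map points.  The recombination rate is the cumulative-cM
difference between the two map points nearest the segment ends, interior
points only, over the fixed 3.6 Mbp — exterior interpolation is rejected
precisely because the denominator is fixed rather than the inter-point
distance.

Per-segment relatedness uses one population-wide baseline: Q̄ over all
pairs of mated parents across all panel SNPs, relative pairs excluded from
the mean (and from the non-mate pair set).  A per-segment baseline was
considered and rejected: it forces every segment's expected mean R to zero
by construction, which erases exactly the signal the scan exists to
expose — a locus whose relatedness is shifted for everyone (e.g. by
elevated diversity under balancing selection) must rank as extreme for
mates *and* non-mates, which is the argument separating locus effects from
mate choice.  Placement is reported in the survival orientation: the
fraction of retained segments whose mean R is greater than or equal to the
query's ("the query is lower than or equal to X% of the genome"), overall
and restricted to segments with recombination rate at or below the
query's.

## Synthetic cohorts

The generator's defaults are the study conditions used throughout the
tests: 30 couples, 2,000 unlinked SNPs on a 36-Mbp chromosome whose
29.7–33.3 Mb interval is the MHC-like locus (~200 SNPs), MAF uniform on
[0.01, 0.5] (a `two_point` mixture preset mimics chips with different
low-frequency coverage), 1% missing calls.  Parents are Hardy–Weinberg
draws; children are Mendelian with independent assortment; planted
relatives (duplicate, parent–offspring, full-sib) occupy male slots of
distinct couples; everything derives from one seed, so identical configs
give byte-identical panels.

Mating preference: candidate couples are weighted by `exp(−β·z)`, where z
is the pair's locus identity standardized against all candidate
male–female pairs, and males (in random order) draw a remaining female by
softmax.  Standardizing is deliberate: raw locus Q varies only by a few
hundredths between candidate pairs (shrinking further with SNP count), so
a weight on raw Q would make the preference strength depend on panel
density and render moderate β values inert.  On the z scale β is
dimensionless — β = 0 is random mating, β ≈ 8 near-deterministically picks
the most dissimilar available partner (median Z ≈ −1.2 at the default
locus).  Only the locus enters the weight, so off-locus identity is
unaffected, and only the "interaction" component of pair identity can
shift the permutation statistic (each individual's main effect is constant
across pairings), which the tests exploit.

What the generator does *not* emulate: linkage disequilibrium (SNPs are
independent, so segment statistics are exchangeable by construction),
population structure and admixture, genotyping error beyond missingness,
assortment on anything but the single locus, and couple ascertainment
(every simulated couple has a child by construction).  Passing tests
therefore establish the correctness and calibration of the *procedure*,
not that real cohorts are free of the confounds these features create.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at the cohort scale
the method targets (30 couples, 2,000-SNP panels; 12,000-SNP four-
chromosome genomes with `min_snps` = 100 for the scan; 2,000-trial
permutation tests, 200 null replicates, 50 preference replicates), chosen
so a full run completes in a couple of minutes on one CPU while leaving
the binomial error of every checked quantity well inside its assertion
band.  Ties in MAF (exactly 0.5/0.5) report 0.5; monomorphic SNPs report
0; exact-tie comparisons in the permutation test use ≥ throughout.  The
Dunn–Šidák α′ is clamped to α at k = 1 to keep the invariant α′ ≤ α exact
in floating point.

## Known limitations

- Identity is genotype-based; haplotype-resolved scoring is out of scope.
- The exclusion enumeration is exact but exponential in the conflict count;
  the cap (64) is a feature, since more permutations than that means the
  relative threshold is misconfigured.
- The scan's low-recombination stratum can be empty for a query in a
  high-recombination region; the placement is then NaN rather than a
  fabricated rank.
- Aggregating P values by arithmetic mean across exclusion permutations is
  a declared convention, not a probability statement; the per-permutation
  range is the honest summary of that uncertainty.
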