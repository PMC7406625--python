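# Methods

This note records the models, conventions and design choices behind
`dormqtl`, in the order the pipeline runs them.

## Genotype representation and QC

Calls are parental-origin codes: `A` donor homozygote, `B` recurrent
homozygote, `H` heterozygote, `-` missing (the only missing code). Marker
coordinates are 1-based bp (VCF convention); all interval output (bins,
ancestry truth, dormancy regions) is BED-style 0-based half-open, stated in
each writer's header. VCF input is polarized by the two parental samples;
markers where a parent is heterozygous, missing, or where both parents
carry the same allele are dropped with a logged count.

Two QC rules run before bin calling. Heterozygous calls are set to missing
in BILs: after seven selfing generations residual heterozygosity is
~0.5·(1/2)^7 ≈ 0.4% per marker, and isolated `H` calls are more often
genotyping noise than true residual heterozygosity. CSSL het calls are kept
as `H` by default (a documented package choice — the window caller treats
them as non-informative either way, so this only affects bookkeeping).
Lines with missing fraction *strictly greater* than 0.20 are excluded;
boundary lines stay. Filtering never reorders or removes markers.

## Bin-map construction

The window rule, per line and chromosome:

* window of 15 SNPs, step 1. A window is called `A` when
  a/(a+b) ≥ a_threshold/(a_threshold+b_threshold) = 12/15 = 0.8 among
  informative (non-`H`, non-missing) calls, `B` when ≤ 0.2, otherwise
  undetermined. The proportional form keeps the 12:3 rule well defined when
  a window contains missing data; windows with fewer than `min_informative`
  (default 8) informative calls are undetermined. Integer arithmetic makes
  the ratio test exact.
* each marker receives the majority vote of the determined windows covering
  it; ties are undetermined. The projection from windows to markers is not
  fixed by the published rule; majority vote is the symmetric choice.
* runs of equal marker calls become blocks. An undetermined run flanked by
  blocks of the same genotype is absorbed into them; one flanked by
  different genotypes is split at the bp midpoint of the run's span (and
  that midpoint is the breakpoint); a leading/trailing undetermined run
  adopts its single neighbour. Directly adjacent blocks of different
  genotype get their breakpoint at the midpoint of the flanking marker gap.
  Midpoints use integer floor division, so breakpoints are integral bp and
  runs of the pipeline are bit-reproducible.
* a chromosome shorter than one window is treated as a single window; a
  line with no determined window on a chromosome becomes one undetermined
  block with no breakpoints (both logged).

The population bin map is the partition of each chromosome at the sorted
unique breakpoint positions of *all* lines; bins run from 0 to the
chromosome length (not marker ends), so they tile exactly and the bin count
per chromosome is (unique breakpoints) + 1. A merge radius for near-equal
breakpoints is available but defaults to 0 bp — published bin maps of this
kind report bins as small as tens of kb, implying no aggressive merging.
Projecting a line's blocks onto the bins is exact by construction (every
line breakpoint is a bin boundary); the projection asserts this and fails
loudly rather than silently resolving a conflict. Summary statistics use
the mean-of-central-values convention for even-count medians.

Equivalence with an independent brute-force implementation of all three
steps (window counts, marker consensus, block/breakpoint derivation) is
enforced in the test suite on random matrices, including missing and het
calls.

## Germination traits

From cumulative counts of n_seeds (default 50) per dish scored at 24 h
intervals to 168 h, with a (t=0, 0) origin prepended:

* G3d = 100·fraction(72 h), G7d = 100·fraction(168 h). If an exact reading
  is absent the nearest prior observation is used (logged).
* AUC = trapezoidal integral of the percentage curve over [0, 168] h
  (units %·h, maximum 16 800). The piecewise-linear interpolant replaces
  parametric curve fitting: it is deterministic, assumption-free, and
  converges to the latent curve's integral as sampling is refined (tested
  against the closed-form logistic integral under grid halving).
* T50 = linear interpolation of the first upward crossing of 50% of the
  *tested* seeds (not of the final germinated count). Lines that never
  reach 50% — precisely the dormant lines of interest — are right-censored
  at 168 h and flagged rather than dropped, so they enter the T50 scan with
  a rank-consistent penalty; a curve already at/above 50% at t=0 gets
  T50 = 0.
* replicates (default 3) are reduced by per-replicate extraction followed
  by arithmetic mean and sample SD (ddof=1); censored replicates contribute
  168 h and set a per-line flag. Extract-then-average is this package's
  convention; the alternative (average curves, then extract) differs near
  censoring.

Invariants asserted in tests: G3d ≤ G7d, AUC ≤ 168·G7d, and invariance to a
redundant duplicated final timepoint.

## Genome scan

Bins are coded A=1, B=0 with per-bin mean imputation of missing calls
(keeps every line in the joint fit without inventing genotypes);
zero-variance bins are dropped and reported. Predictors are standardized
and the trait centered.

The scan is a single joint ridge regression of the trait on all bins —
substitution-panel bins are strongly collinear, and a joint shrunk fit is
the standard alternative to marker-by-marker testing. The penalty is chosen
by seeded 5-fold cross-validation over a 40-point log grid (1e-2..1e5),
computed via one SVD per fold so the grid is effectively free.
Leave-one-out/GCV selection is deliberately not used: with more bins than
lines it sits in the interpolation (double-descent) regime and sometimes
selects a vanishing penalty, which destroys the scan. A fixed penalty can
be supplied instead.

Per-bin p-values are pointwise permutation tests: the trait vector is
permuted B times (default 2000, minimum 100) with the penalty held fixed,
coefficients for all permutations come from the same SVD at the cost of one
matrix product, and the p-value of bin j is (1 + #{|coef_perm| ≥
|coef_obs|})/(B+1). Holding the CV penalty fixed across permutations keeps
the statistic's null distribution exchangeable and is ~B times cheaper than
re-running CV per draw. An analytic normal-theory alternative (`ridge-t`,
using effective degrees of freedom) is provided and labelled approximate.
Coefficient signs are reported as allele direction: positive means the
donor allele increases the trait.

QTL declaration collapses each maximal run of adjacent bins with p < alpha
(default 0.005, the study-style fixed threshold; no multiple-testing
correction beyond it) to one record at the lowest-p bin. Permutation
p-values are discrete with floor 1/(B+1), so strong bins tie routinely; the
peak among tied bins is the one with the largest *marginal* association
|corr(bin, trait)| — under heavy shrinkage the joint ridge coefficients
apportion signal among collinear bins arbitrarily, whereas the marginal
peak is the conventional localization statistic — with residual ties broken
toward the lower coordinate. Dropped (zero-variance) bins break adjacency.
Names are q<trait><chrom>.<serial>, serials by position within chromosome.

PVE per declared QTL is the LMG share on an OLS refit of the peak bins:
each predictor's average sequential R² increment over predictor orderings,
computed exactly over all 2^p subsets for p ≤ 15 and by Monte-Carlo over
orderings beyond that. Shares are non-negative and sum to the full-model R²
(asserted to 1e-9). Perfectly collinear duplicates (|r| ≥ 1 − 1e-12) are
merged onto their first occurrence before decomposition and logged.

Cross-trait clustering groups QTLs whose contiguous significant spans
overlap; components with ≥ 3 distinct traits become dormancy regions
(qSD<chrom>.<serial>), with a flag when all four traits agree. Spans — not
single peak bins — define overlap: peak bins from one bin map can only
overlap when identical, which would make the clustering fragile to one-bin
peak wander between traits.

## F2 statistics and epistasis

Single-marker analysis at a codominant marker with classes AA (donor hom),
AB, BB: a = (mean(AA) − mean(BB))/2, d = mean(AB) − (mean(AA)+mean(BB))/2,
p from one-way ANOVA, PVE = 100·SS_between/SS_total, LOD =
(n/2)·log10(SS_total/SS_residual). Absent classes leave the affected effect
undefined while the rest is still reported; zero residual variance yields
PVE = 100, p = 0, infinite LOD.

Two-locus epistasis is a fixed-effects two-way ANOVA with interaction on
the ≤ 9 genotype classes, using Type-II sums of squares (F2 class
frequencies are inherently unbalanced at 1:2:1, and Type II does not depend
on an arbitrary ordering of the two main effects). Empty cells reduce the
interaction degrees of freedom; the table notes this. Per-class counts and
means accompany the ANOVA rows.

## The simulator

What it emulates:

* **Meiosis** under the Haldane model — crossover counts Poisson with mean
  map length/100 cM, positions uniform in cM, no interference — with a
  linear physical↔genetic scaling, default 270 kb/cM (rice-typical),
  configurable. Haldane was chosen for its closed form; interference mainly
  affects the segment-length distribution, not the expectations the tests
  rely on.
* **BILs**: one backcross of the F1 to the recurrent parent, then
  single-seed-descent selfing (default 7 generations, BC1F1→F8). Donor
  allele frequency 1/4 and per-generation halving of heterozygosity follow
  without further assumptions and are verified by simulation tests.
* **CSSLs**: the real breeding scheme (several marker-assisted backcross
  generations, unpublished in detail) is not re-enacted; candidates are
  generated by repeated backcrossing (default 4) of the introgressed
  haplotype, fixed by doubling, filtered to 1..max_donor_segments (default
  3) homozygous donor segments, and greedily selected (lazy submodular
  maximum-coverage, deterministic tie-breaks) to tile the genome. The
  endpoint — one-to-few donor segments per line, high panel coverage — is
  what downstream analysis sees; pedigree-specific segment-length
  distributions are not reproduced.
* **F2**: one selfing of the F1.
* **Germination**: each line has a latent curve G(t) = Gmax·σ((t−t50)/slope)
  with logistic germination times, a point mass of 1−Gmax at "never", and
  integer cumulative counts of n_seeds = 50 per dish at 24 h intervals over
  7 days, 3 replicate dishes per line. QTL effects act additively on the
  latent parameters (recurrent hom 0, het a+d, donor hom 2a; epistasis as
  an additive-by-additive term aa·(x1−1)(x2−1) on dosages x ∈ {0,1,2}), so
  the four traits inherit their characteristic correlation structure (G3d,
  G7d, AUC positively correlated, all negative with T50) without being
  targeted directly; trait-targeted effect specifications are rejected.
  Line-level environmental noise (default SD 10 h on t50, 0.07 on Gmax) is
  drawn once per line; replicate dishes share the line's latent curve and
  differ only by seed sampling. Gmax is clipped to [0,1] with a logged
  warning if effects push it outside.

Default planted effects for the bundled 400-line fixture: three t50 QTLs of
a = 6.5 h (donor homozygote +13 h) and one Gmax QTL of a = −0.04, at the
midpoints of chromosomes 1–4. With the default noise model each contributes
roughly 10–20% of its primary trait's variance (the t50 additive effect was
set from the closed-form share (2a)²·3/16 of the total t50 variance ≈ 16%);
the acceptance script measures the realized values. The tiny fixture
(2 chromosomes × 30 markers, 40 lines) carries a single t50 QTL and exists
for fast calibration checks.

What the simulator does *not* model: after-ripening and dormancy-breaking
treatments, ABA dose–response, genotype×environment interaction, field
structure, segregation distortion, genotyping error beyond missingness, and
marker ascertainment. Passing recovery tests therefore demonstrates the
correctness and calibration of the pipeline under its stated genetic model,
not robustness to every artefact of real panels.

All randomness flows from one integer seed through named, counter-based
substreams (`numpy` `SeedSequence` spawn keys from crc32 of stage names),
so any stage can be re-run independently and whole runs are byte-identical
for a given configuration and seed.

## Numerical conventions and degenerate inputs

* Window ratio tests in integer arithmetic; breakpoint midpoints by floor
  division; all tie-breaks deterministic (documented above).
* A window with zero informative calls is always undetermined, independent
  of `min_informative`.
* Constant traits and panels of fewer than 30 phenotyped lines are rejected
  by the scanner; missing trait values drop the line from that trait's scan.
* LMG conservation is asserted at 1e-9; germination closed forms at 1e-9.
* Decreasing cumulative counts or counts above n_seeds are rejected as
  corrupt input rather than repaired.

## Known limitations

* Permutation p-values floor at 1/(B+1); with the fixed 0.005 threshold, B
  must be ≥ 200 for any declaration, and peak choice within runs tied at
  the floor relies on the marginal statistic.
* The scan's localization unit is the bin; in dense maps adjacent bins are
  near-identical and peak positions wander by a bin or two around strong
  QTLs — the recovery tests quantify this at the fixture scale.
* Adjacency for QTL collapse is strict: a single non-significant bin splits
  a region into two records.
* The ridge-t p-values are approximate (shrinkage biases the normal-theory
  SEs) and are provided for comparison only; output tables record which
  method produced them.
* CSSL simulation matches the endpoint, not the pedigree; quantities that
  depend on the exact breeding path (e.g. the distribution of donor segment
  lengths) should not be read off the simulator.
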