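# Methods

This note records the models, estimators and design choices behind
`sibscan`, in the spirit of a statistical methods appendix: what is assumed,
what is tunable, and what the synthetic cohorts do and do not emulate.

## Study designs supported

Two contrast designs drive the association machinery.

**Interpair** contrasts compare two disjoint sets of sibling pairs —
canonically the mildest concordant pairs (CON+) against the severest
concordant pairs (CON−). Both sibs of a pair share the group label, so the
exchangeable unit under the null is the *pair*, and the permutation engine
reassigns whole pairs between groups while preserving group sizes. (A
naive individual-level permutation would break the intra-pair genotype
correlation and anti-conservatively narrow the null; this is a deliberate
design choice.)

**Intrapair** contrasts compare the mild sib with the severe sib within
discordant (DIS) pairs. Here the null hypothesis is that severity labels are
exchangeable *within* a pair, so the reference distribution swaps mild and
severe designations independently per pair with probability ½. This
conditions on everything a pair shares — parents, environment, and the pair's
genotypes as an unordered set.

## Severity ranking and pair selection

Each patient receives ascending ranks (average on ties) for the two severity
traits, weight as % of predicted weight-for-height and the CF-population
centile of FEV1%pred; higher is milder on both. The composite is the
unweighted rank sum, so selection is invariant to any strictly monotone
rescaling of either trait. DIS pairs are the `n_dis` with the largest
absolute intrapair composite difference; they are removed before CON+ (largest
pair mean) and CON− (smallest pair mean) are drawn, making the three groups
disjoint by construction. All ties break on family id, lexicographically, so
the selection is a pure deterministic function of the input. The pipeline
consumes one summary value per trait per patient; longitudinal aggregation is
upstream of this package.

## EM haplotype frequencies

For a window of w markers (2^w haplotype states; the scan uses w ≤ 2, the
implementation accepts up to 12), each individual's unphased genotype is
compatible with a set of ordered haplotype pairs: heterozygous markers split
phases, missing markers sum over both alleles on both chromosomes.
Individuals missing every call in the window are dropped from that window's
likelihood. The EM iteration is the standard one — posterior weights
f(h₁)f(h₂) normalized over the compatible set, then f(h) ∝ expected count
over 2N chromosomes — with:

* tolerance `tol = 1e-8` on the max absolute frequency change,
  `max_iter = 1000`;
* deterministic uniform initialization by default; an optional
  10-restart random (Dirichlet) mode keeps the best final likelihood, a guard
  against local maxima that matters only for wide windows;
* frequencies below 1e-12 pruned from the *report* (the full vector is kept
  for LD computation);
* log-likelihood non-decrease asserted per iteration in the test suite (an
  EM guarantee; a violation would indicate an implementation bug).

A uniform start on a single double-heterozygote is an exact fixed point at
(¼,¼,¼,¼) — the symmetric saddle — which the tests pin down as a boundary
behaviour, not a defect: with no phase information the likelihood is flat
between the two phase explanations.

Sib pairs are treated as independent individuals during frequency
estimation, and group tests fit the pooled sample (both groups together) as
the shared reference; this "shared EM" convention keeps rare-haplotype
assignment consistent across subsamples. The cost is a mild downward bias in
frequency-variance estimates when many sib pairs are present; the permutation
machinery, which preserves pairs, is what carries inferential weight.

## Window tests and multiple-testing correction

Single markers are tested by Pearson χ² on the 2×2 allele-count table
(1 df, no continuity correction; zero-margin tables return p = 1 with a
degeneracy flag). 2-marker windows use the likelihood-ratio statistic
2[ℓ_A + ℓ_B − ℓ_pool] with df = H − 1, where H counts haplotypes with pooled
frequency above 1e-6 — rarer EM dust is not allowed to inflate df.

The asymptotic χ² reference for this LRT is accurate in the ~100-per-group
regime and mildly conservative for very small groups (boundary-constrained
frequencies); the test suite checks null uniformity at 200 per group. This
small-sample conservatism is one reason the *reported* family-wise number is
permutation-based:

* The scan family is all single markers plus all adjacent (optionally all
  non-adjacent) 2-marker windows over the informative-marker list
  (observed MAF strictly > threshold; default 0.4).
* Pbest is the minimum Praw over the family.
* `permutation_correct` re-tests the whole family in each of R replicates
  (default 10,000 in the CLI, enough to resolve p ~ 1e-3 comfortably),
  converts every window's statistics to shared-pool Monte-Carlo p-values,
  and reports Pcorr = (1 + #{min-p_replicate ≤ min-p_observed}) / (R + 1).
  This min-p construction handles the heterogeneous family (χ² with 1 df
  next to LRTs with varying df) that a raw max-statistic rule could not,
  and guarantees Pcorr ≥ 1/(R+1) and Pcorr ≥ the observed min-p.

Type-I calibration of the full pipeline (simulate → rank → select → scan →
correct) is verified empirically: across 500 null cohorts the fraction with
Pcorr < 0.05 at R = 200 falls inside [0.03, 0.07].

Intrapair per-window Praw is itself Monte-Carlo (within-pair swaps,
+1-corrected, so never exactly 0); an exhaustive mode enumerates all 2^n swap
patterns for n ≤ 16 pairs and serves as the exactness oracle for the MC
path.

## Fragments, consensus, and risk-allele annotation

Fragment assignment uses the per-window Praw (the paper-style per-window
quantity), not Pcorr: maximal runs of consecutive adjacent 2-marker windows
with Praw < α (default 0.05) merge into fragments named by their terminal
markers, closed on both ends in map order. The consensus operation
intersects interpair and intrapair fragment intervals; requiring the two
independent contrasts to agree is the fine-mapping step that shrinks the
candidate region.

The consistent-difference filter takes a resequencing alignment of
haplotypes labelled severe/mild and returns the markers at which the two
classes are internally fixed and mutually different — optionally restricted
to the mapped fragment. Risk-allele annotation votes per contrast (the
allele more frequent in the severe group); the overall call is the unanimous
vote and any tie or disagreement clears the consistency flag.

## Survivor-effect diagnostics

Strata are formed by a birth-year split (an explicit year, or the cohort
median with ties to the earlier stratum) and an optional filter on the
cohort-wide FEV1-centile median. Per stratum the index-marker genotype and
allele counts feed (a) the conditional exact Hardy–Weinberg test —
probability-ordered two-sided p given the allele counts, chosen over the χ²
approximation because the motivating strata have n ≈ 33 — with the signed
direction of the heterozygote deviation reported, and (b) a fixed-margins
Monte-Carlo Pearson χ² between strata (multivariate-hypergeometric null
draws, +1-corrected p). The Monte-Carlo contingency test is the plain
raw-table statistic; rare-cell clumping variants are out of scope.

## Expression comparison

Welch's two-sample t (Welch–Satterthwaite df) is the default because no
equal-variance assumption is warranted; a pooled-variance mode exists. The
default grouping contrasts carriers vs non-carriers of a named allele, since
a dominant-style carrier effect is the natural first read of an
expression-raising allele; all three genotype means are always reported and a
pairwise-genotype mode is exposed, so the grouping ambiguity is surfaced
rather than hidden. Groups with fewer than 2 samples skip their contrast
with an explicit report.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the suite assumes.

* **Founder pool:** markers partition into contiguous LD blocks; within a
  block only `haplos_per_block` distinct strings exist (forcing pairwise D′
  = 1 within the block), blocks combine with free recombination, and every
  marker's pool MAF is drawn into (0.2, 0.5] — (0.3, 0.5] in the scan tests,
  mirroring a deliberately informative marker panel. Block frequencies are
  mildly jittered Dirichlet draws around uniform.
* **Transmission:** 4 founder haplotypes per family, one transmitted per
  parent per child independently, *no recombination within the locus* — the
  locus spans tens of kb, where recombination within one meiosis is
  negligible. Missingness is uniform at `missing_rate`.
* **Phenotypes:** latent trait = −effect_size × (risk-allele dosage at the
  causal marker) + pair-shared Gaussian effect (sd `family_effect_sd`,
  shared across sibs and traits — the shared-environment term) + individual
  noise, with the two traits' noises correlated at `trait_correlation`
  (default 0.5; the two clinical severity axes are correlated but not
  redundant). Latent traits map to the reported scales by empirical cohort
  rank — the analysis consumes only ranks/centiles, so reference-equation
  realism is unnecessary. Defaults: effect_size 1.0 (a strong modifier, as
  an extreme-phenotype design presupposes), family_effect_sd 0.5.
* **Survivorship:** patients born before the split year are retained with
  probability logistic(−steepness × risk dosage); later births always
  enroll. Retention acting before "enrollment" makes the returned cohort the
  cross-sectionally recruited one. Note logistic(0) = ½: even non-carriers
  face the (severe) historical early-cohort mortality.
* **Expression:** baseline + effect × benign-allele dosage + Gaussian noise.

One `seed` fixes every stage bit-for-bit (stage-tagged child generators).
With effect 0 and steepness 0 the generator is an exact null, which the
type-I calibration consumes.

What the generator does **not** emulate: coalescent/mutational realism,
genotyping error beyond uniform missingness, recombination within the locus,
age- or treatment-era-dependent phenotype drift, pedigree structures beyond
two full sibs. Passing tests therefore demonstrate the statistical machinery
under the design's stated assumptions, not robustness to those violations.

## Numerical conventions

* Monte-Carlo p-values use the +1 estimator everywhere: p = (1 + #{replicate
  ≥ observed}) / (R + 1); they are never 0.
* Statistic comparisons against replicates use a 1e-9 absolute slack so that
  EM convergence noise cannot flip a tie.
* D′ and r² are clamped to [0, 1] against rounding; LD is an error (not NaN)
  for monomorphic margins, and a monomorphic adjacent pair closes a
  haplotype block with a logged warning.
* MAF thresholds compare strictly (`>`), so "MAF > 0.4" excludes exactly 0.4.
* Scan reports serialize numbers with 10 significant digits; round-trips
  reproduce Praw to better than 1e-10 relative error.

## Problem sizes in the standard checks

The bundled verification suites run at desk scale: 500 null cohorts of 20
pairs (R = 200) for type-I calibration; 100 cohorts of 250 pairs with 50
pairs per selected group for causal-fragment recovery; 8 pairs for
exhaustive-swap comparisons; ~500 enrolled patients per birth cohort for the
survivor signature; n ≤ 10 tables for exhaustive Hardy–Weinberg checks.
These sizes were chosen to make Monte-Carlo error small relative to the
assertion margins while keeping the whole suite runnable in minutes.

## Known limitations

* The 2-marker LRT's asymptotic p is conservative for very small groups;
  family-wise claims should rest on Pcorr (permutation), which is exact in
  distribution given the design.
* Haplotype-frequency estimation treats sibs as independent; only the
  permutation layer accounts for the pair structure.
* Fragment assignment is threshold-based (Praw < α per window) and inherits
  the granularity of the marker panel: a causal variant between two
  uninformative markers cannot be localized more finely than the spanning
  window.
* The survivor model is a single-locus logistic retention; real survivorship
  acts on the whole genome and on environment jointly.
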