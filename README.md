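# sibscan

Haplotype fine-mapping of disease-modifier loci from **extreme-phenotype
sibling pairs**, with survivor-effect diagnostics for cross-sectionally
recruited cohorts.

## The problem

In a monogenic disease such as cystic fibrosis, secondary ("modifier") genes
shift disease severity, but their effects are small and easily swamped by
non-genetic confounders (birth cohort, access to care, socioeconomic status).
Two design ideas make small, carefully characterized cohorts informative:

* **Extreme sibling pairs.** Siblings share environment and (here) the same
  disease-causing genotype, so contrasting *concordant-mild* (CON+) against
  *concordant-severe* (CON−) pairs — and the mild against the severe sib
  *within* discordant (DIS) pairs — isolates inherited modifiers.
* **Survivor diagnostics.** Cross-sectional recruitment only genotypes
  survivors, so alleles that promote survival are enriched among early-born
  patients; stratifying by birth cohort makes that drift (and the
  accompanying Hardy–Weinberg distortion) visible instead of letting it
  masquerade as, or mask, association.

`sibscan` implements the full pipeline: composite severity ranking and
extreme-pair selection, EM haplotype-frequency estimation from unphased
genotypes, a sliding single-marker / 2-marker haplotype association scan with
min-p permutation correction, fragment assignment and cross-contrast
consensus, risk-allele annotation, Hardy–Weinberg and birth-cohort
diagnostics, and expression-by-genotype comparison — plus a synthetic-cohort
generator that reproduces the statistical structure the analysis assumes, so
every stage is testable without any external data.

## The statistics at the core

* **Composite severity rank.** Each patient gets ascending ranks for weight
  (% predicted weight-for-height) and for the CF-population centile of
  FEV1%pred; the composite is the unweighted rank sum. Pairs are selected by
  intrapair discordance |c₁ − c₂| (DIS) and pair mean (CON+/CON−).
* **EM haplotype frequencies.** For a marker window, each individual's
  unphased genotype is a mixture over compatible ordered haplotype pairs
  (h₁,h₂); the E-step weights each pair by f(h₁)f(h₂) normalized over the
  compatible set, the M-step sets f(h) ∝ expected count over 2N chromosomes.
  Missing calls are summed over; the log-likelihood is provably
  non-decreasing (asserted in tests).
* **Window tests.** Single markers: Pearson χ² on the 2×2 allele table.
  2-marker windows: likelihood-ratio statistic
  2[ℓ_A(f̂_A) + ℓ_B(f̂_B) − ℓ_pool(f̂_pool)]. Interpair contrasts report the
  asymptotic p as Praw; intrapair contrasts report a Monte-Carlo p from
  within-pair label swaps (each pair swapped independently with probability
  ½, +1-corrected).
* **Family-wise correction.** Pbest = min Praw over the tested family. Pcorr
  comes from a min-p (max-statistic) permutation scheme whose exchangeable
  unit respects the design: whole pairs are reassigned between groups for
  interpair contrasts, within-pair swaps for intrapair contrasts; each
  replicate re-tests the entire window family.
* **LD and blocks.** D = p(AB) − p(A)p(B), D′ = |D|/D_max, r² = D²/(p_A p_a
  p_B p_b); haplotype blocks are maximal runs of adjacent pairs with
  D′ above a threshold (default 0.8).
* **Survivor diagnostics.** Conditional exact Hardy–Weinberg test
  (probability-ordered two-sided p, with the deviation direction), and a
  fixed-margins Monte-Carlo χ² for comparing genotype/allele tables across
  birth-cohort strata.
* **Expression.** Welch's t (pooled-variance optional) between carriers and
  non-carriers of an allele, or across all genotype pairs.

## Worked example

Simulate a study-sized cohort (114 sibling pairs, 9 SNPs in 3 LD blocks, an
additive causal variant at `snp005`), select the 14 most discordant, 11
mildest-concordant and 10 severest-concordant pairs, and scan:

```bash
sibscan simulate --out-prefix demo --n-pairs 114 --n-markers 9 \
    --effect-size 1.2 --seed 11
sibscan rank-pairs --phenotypes demo.pheno.csv --out demo.cls.tsv
sibscan scan --ped demo.ped --map demo.map --classification demo.cls.tsv \
    --maf-threshold 0.2 --permutations 2000 --seed 11 --out-prefix demo.inter
sibscan scan --ped demo.ped --map demo.map --classification demo.cls.tsv \
    --mode intrapair --maf-threshold 0.2 --permutations 2000 --seed 11 \
    --out-prefix demo.intra
sibscan expression --expression demo.expr.csv \
    --grouping carrier_vs_noncarrier --allele A --out demo.expr.tsv
```

which prints

```
wrote demo.ped/.map/.pheno.csv/.expr.csv/.truth.json
wrote demo.cls.tsv (selected: {'unselected': 79, 'DIS': 14, 'CON+': 11, 'CON-': 10})
Pbest = 8.19126e-11; Pcorr = 0.00049975; 1 fragment(s)
Pbest = 0.0049975; Pcorr = 0.0184908; 2 fragment(s)
wrote demo.expr.tsv (genotype means: AA: 7.964, AG: 7.498, GG: 6.977)
```

Reading the output: the interpair contrast (CON+ vs CON−) reaches
Pbest = 8.2e-11 with family-wise Pcorr = 0.0005 (2000 pair-label
permutations, floor 1/2001), and its significant adjacent windows merge into
the fragment `snp003–snp007`; the intrapair contrast independently maps
`snp003–snp006`. Their consensus contains the true causal marker `snp005`
(recorded in `demo.truth.json`). The expression contrast shows the benign
allele A raising expression by ~0.5 units per copy (t = 8.8, p = 3.3e-16),
the dosage pattern visible in the three genotype means.

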