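"""Survivor-effect diagnostics on unrelated patient cohorts.

In a cross-sectional recruitment only patients alive at enrollment are
genotyped, so alleles that promote survival are enriched among early-born
patients.  The diagnostics here make that signature visible: stratify the
cohort by birth year (and optionally by initial lung function), tabulate
genotype and allele counts at an index marker per stratum, test each stratum
for Hardy-Weinberg equilibrium with the conditional exact test, and compare
strata with a Monte-Carlo contingency chi-square (fixed margins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("sibscan")


@dataclass
class CohortStratification:
    """Genotype and allele counts at the index marker for one stratum."""

    stratum_label: str
    sample_ids: list[str]
    genotype_counts: dict[str, int]  # {"AA": n, "AB": n, "BB": n}
    allele_counts: dict[str, int]

    def counts_tuple(self) -> tuple[int, int, int]:
        g = self.genotype_counts
        keys = list(g.keys())
        return g[keys[0]], g[keys[1]], g[keys[2]]


def _counts_at_marker(genotypes: GenotypeMatrix, sample_ids, marker_id: str):
    a, b = genotypes.markers.alleles(marker_id)
    b = b if b is not None else "?"
    j = genotypes.markers.index_of(marker_id)
    dos = genotypes.dosage[genotypes.sample_index(sample_ids), j]
    called = dos != MISSING
    n_bb = int((dos[called] == 2).sum())
    n_ab = int((dos[called] == 1).sum())
    n_aa = int((dos[called] == 0).sum())
    genotype_counts = {a + a: n_aa, a + b: n_ab, b + b: n_bb}
    allele_counts = {a: 2 * n_aa + n_ab, b: 2 * n_bb + n_ab}
    return genotype_counts, allele_counts


def stratify_cohort(phenotypes: PhenotypeTable, genotypes: GenotypeMatrix,
                    index_marker: str, split_year="median",
                    fev1_split: str = "all") -> list[CohortStratification]:
    """Partition by birth-year split and FEV1-median filter; count genotypes.

    ``split_year`` is an integer year or ``"median"`` (cohort median birth
    year; birth years <= the split go to the early stratum).  ``fev1_split``
    keeps only patients above ("above") or at/below ("below") the cohort-wide
    FEV1 centile median, or everyone ("all"); the median is computed on the
    whole cohort with ties assigned to the lower stratum.  Empty strata are
    reported with zero counts, not an error.
    """
    df = phenotypes.data
    if split_year == "median":
        split = int(np.median(df["birth_year"].to_numpy()))
    else:
        split = int(split_year)
    if fev1_split not in ("above", "below", "all"):
        raise ValueError("fev1_split must be 'above', 'below' or 'all'")
    fev1_median = float(np.median(df["fev1_centile"].to_numpy()))
    if fev1_split == "above":
        df = df[df["fev1_centile"] > fev1_median]
        fev1_tag = f", FEV1 above median ({fev1_median:g})"
    elif fev1_split == "below":
        df = df[df["fev1_centile"] <= fev1_median]
        fev1_tag = f", FEV1 at/below median ({fev1_median:g})"
    else:
        fev1_tag = ""
    strata = []
    for label, sub in (
            (f"born <= {split}{fev1_tag}", df[df["birth_year"] <= split]),
            (f"born > {split}{fev1_tag}", df[df["birth_year"] > split])):
        sids = sub["sample_id"].tolist()
        if sids:
            geno, alle = _counts_at_marker(genotypes, sids, index_marker)
        else:
            a, b = genotypes.markers.alleles(index_marker)
            b = b if b is not None else "?"
            geno = {a + a: 0, a + b: 0, b + b: 0}
            alle = {a: 0, b: 0}
        strata.append(CohortStratification(
            stratum_label=label, sample_ids=sids,
            genotype_counts=geno, allele_counts=alle))
    return strata


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_het_prob(n_het: int, n_a: int, n: int) -> float:
    """P(heterozygote count | minor-allele count n_a, sample size n) under HWE.

    Standard conditional distribution: P(h) = n! / (h_AA! h! h_BB!) *
    2^h * n_a! n_b! / (2n)! with h_AA = (n_a - h)/2, h_BB = n - h_AA - h.
    Computed in log space.
    """
    n_b = 2 * n - n_a
    if (n_a - n_het) % 2 != 0 or n_het > min(n_a, n_b) or n_het < 0:
        return 0.0
    n_aa = (n_a - n_het) // 2
    n_bb = (n_b - n_het) // 2
    log_p = (math.lgamma(n + 1) - math.lgamma(n_aa + 1) - math.lgamma(n_het + 1)
             - math.lgamma(n_bb + 1) + n_het * math.log(2)
             + math.lgamma(n_a + 1) + math.lgamma(n_b + 1) - math.lgamma(2 * n + 1))
    return math.exp(log_p)


@dataclass
class HWEResult:
    p_value: float
    n_het_observed: int
    n_het_expected: float
    direction: str  # "heterozygote excess" | "heterozygote deficit" | "none"


def hwe_exact_test(genotype_counts) -> HWEResult:
    """Conditional exact Hardy-Weinberg test.

    ``genotype_counts`` is (n_AA, n_AB, n_BB) or a mapping whose values are
    taken in that order.  Given the allele counts, all heterozygote counts of
    matching parity are enumerated and weighted by the conditional
    distribution; the p-value sums the probabilities of outcomes no more
    probable than the observed one (two-sided by probability ordering).
    The signed direction of the observed deviation is reported alongside.
    """
    if isinstance(genotype_counts, dict):
        vals = list(genotype_counts.values())
    else:
        vals = list(genotype_counts)
    if len(vals) != 3:
        raise ValueError("need exactly three genotype counts")
    n_aa, n_het, n_bb = (int(v) for v in vals)
    if min(n_aa, n_het, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_het + n_bb
    if n < 1:
        raise ValueError("total count must be >= 1")
    n_a = 2 * n_aa + n_het
    n_b = 2 * n_bb + n_het
    n_minor = min(n_a, n_b)
    expected_het = n_a * n_b / (2.0 * n) if n > 0 else 0.0
    if n_minor == 0:
        return HWEResult(p_value=1.0, n_het_observed=n_het,
                         n_het_expected=expected_het, direction="none")
    p_obs = _hwe_het_prob(n_het, n_minor, n)
    p_value = 0.0
    for h in range(n_het % 2, n_minor + 1, 2):
        p_h = _hwe_het_prob(h, n_minor, n)
        if p_h <= p_obs * (1 + 1e-12):
            p_value += p_h
    p_value = min(p_value, 1.0)
    if n_het > expected_het:
        direction = "heterozygote excess"
    elif n_het < expected_het:
        direction = "heterozygote deficit"
    else:
        direction = "none"
    return HWEResult(p_value=p_value, n_het_observed=n_het,
                     n_het_expected=expected_het, direction=direction)


# ---------------------------------------------------------------------------
# Monte-Carlo contingency test (fixed margins)
# ---------------------------------------------------------------------------

@dataclass
class MCContingencyResult:
    statistic: float
    p_value: float
    n_replicates: int


def _pearson_chi2_k2(col1: np.ndarray, row_tot: np.ndarray, n1: float, n2: float):
    """Chi-square of a K x 2 table given column-1 counts (vectorized over rows
    of ``col1``); rows with zero margin contribute 0."""
    col1 = np.atleast_2d(col1).astype(float)
    N = n1 + n2
    e1 = row_tot[None, :] * (n1 / N)
    e2 = row_tot[None, :] * (n2 / N)
    col2 = row_tot[None, :] - col1
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(e1 > 0, (col1 - e1) ** 2 / e1, 0.0)
        t2 = np.where(e2 > 0, (col2 - e2) ** 2 / e2, 0.0)
    return (t1 + t2).sum(axis=1)


def mc_contingency_test(table, R: int, seed: int | None) -> MCContingencyResult:
    """Monte-Carlo Pearson chi-square on a K x 2 table with both margins fixed.

    The observed statistic is computed on the raw table without continuity
    correction; null tables are drawn by a multivariate hypergeometric
    distribution (equivalent to permuting column labels across observations),
    and p = (1 + #{replicate chi2 >= observed}) / (R + 1).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("table must be K x 2 with K >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n1, n2 = t.sum(axis=0)
    if n1 < 1 or n2 < 1:
        raise ValueError("both column sums must be >= 1")
    row_tot = t.sum(axis=1)
    obs = float(_pearson_chi2_k2(t[:, 0], row_tot, n1, n2)[0])
    rng = np.random.default_rng(seed)
    reps = np.array([rng.multivariate_hypergeometric(row_tot, n1) for _ in range(R)])
    rep_stats = _pearson_chi2_k2(reps, row_tot, n1, n2)
    p = float((1 + np.sum(rep_stats >= obs - 1e-9)) / (R + 1))
    return MCContingencyResult(statistic=obs, p_value=p, n_replicates=R)


def exhaustive_contingency_p(table) -> float:
    """Exact fixed-margins p for a K x 2 table by full enumeration.

    Oracle for :func:`mc_contingency_test` at small margins: enumerates every
    table with the observed margins, weights it by the multivariate
    hypergeometric probability, and sums the mass of tables whose chi-square
    is at or above the observed one.
    """
    t = np.asarray(table, dtype=int)
    row_tot = t.sum(axis=1)
    n1, n2 = t.sum(axis=0)
    obs = float(_pearson_chi2_k2(t[:, 0], row_tot, n1, n2)[0])
    K = len(row_tot)

    def log_comb(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    total_log = log_comb(n1 + n2, n1)
    p = 0.0

    def recurse(i, remaining, col1, acc_log):
        nonlocal p
        if i == K:
            if remaining == 0:
                stat = float(_pearson_chi2_k2(np.array(col1), row_tot, n1, n2)[0])
                if stat >= obs - 1e-9:
                    p += math.exp(acc_log - total_log)
            return
        lo = max(0, remaining - int(row_tot[i + 1:].sum()))
        hi = min(row_tot[i], remaining)
        for c in range(lo, hi + 1):
            recurse(i + 1, remaining - c, col1 + [c],
                    acc_log + log_comb(row_tot[i], c))

    recurse(0, int(n1), [], 0.0)
    return min(p, 1.0)


def strata_comparison_table(strata: list[CohortStratification],
                            kind: str = "allele") -> np.ndarray:
    """K x 2 table of allele (or genotype) counts across two strata."""
    if len(strata) != 2:
        raise ValueError("need exactly two strata")
    key = "allele_counts" if kind == "allele" else "genotype_counts"
    c0, c1 = getattr(strata[0], key), getattr(strata[1], key)
    cats = list(c0.keys())
    return np.array([[c0[c], c1.get(c, 0)] for c in cats], dtype=int)
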