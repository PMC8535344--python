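"""Synthetic sib-pair cohorts with the structure the association scan assumes.

The generator emulates the study conditions of an extreme-phenotype CF
modifier scan: LD-block-structured founder haplotypes over a short locus with
high-MAF markers, Mendelian transmission to affected sibling pairs (no
recombination within the locus), a biallelic causal variant with an additive
effect on two correlated severity traits (weight-for-height %, FEV1
CF-population centile), genotype-dependent survivorship across birth cohorts,
and allele-dosage-dependent expression with Gaussian noise.

Conventions: at every marker ``allele_b`` of the map is the "risk" allele in
the sense that the causal effect and the survivorship penalty act on the
dosage of allele_b at ``causal_marker``; ``allele_a`` is the benign allele.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import (MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable,
                         ValidationError)

logger = logging.getLogger("sibscan")

#: allele pairs cycled across markers (alphabetical, so PED round-trips keep
#: the allele_a/allele_b orientation)
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]

# sub-stream tags so that one SimulationConfig.seed fixes every stage
_STREAM_POOL, _STREAM_FAMILIES, _STREAM_PHENO, _STREAM_SURV, _STREAM_EXPR = range(5)


class ConfigurationError(ValueError):
    """Inconsistent simulation request."""


@dataclass
class FounderHaplotypePool:
    """Founder haplotype distribution over the whole locus.

    Haplotypes are allele strings over all markers; ``block_boundaries``
    holds the start index of each LD block.  Within a block diversity is
    restricted to a few strings (forcing high D'); across blocks haplotypes
    combine with free recombination, so the full-locus frequencies are
    products of block frequencies.
    """

    markers: MarkerMap
    haplotypes: list[str]
    frequencies: np.ndarray
    block_boundaries: list[int]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != len(self.frequencies):
            raise ConfigurationError("haplotype/frequency length mismatch")
        if np.any(self.frequencies < 0) or abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ConfigurationError("frequencies must be >= 0 and sum to 1")
        n = self.markers.n_markers
        if any(len(h) != n for h in self.haplotypes):
            raise ConfigurationError("haplotype length != marker count")

    @property
    def dosage_matrix(self) -> np.ndarray:
        """(n_haplotypes, n_markers) 0/1 indicator of allele_b."""
        tab = self.markers.table
        out = np.zeros((len(self.haplotypes), self.markers.n_markers), dtype=np.int8)
        for j in range(self.markers.n_markers):
            b = tab.allele_b[j]
            for i, h in enumerate(self.haplotypes):
                out[i, j] = 1 if (b is not None and h[j] == b) else 0
        return out

    def marker_allele_b_freq(self, j: int) -> float:
        return float(self.frequencies @ self.dosage_matrix[:, j])


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator.

    effect_size: standardized additive decrease in each latent severity trait
    per risk allele (positive = risk allele worsens disease).
    trait_correlation: correlation of the two traits' individual noises.
    family_effect_sd: sd of the pair-shared random effect (shared environment).
    survival_steepness: per-risk-allele log-odds of pre-enrollment death in
    the early birth cohort.
    """

    n_pairs: int
    causal_marker: str
    effect_size: float = 1.0
    trait_correlation: float = 0.5
    family_effect_sd: float = 0.5
    missing_rate: float = 0.0
    survival_steepness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        for name in ("missing_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.trait_correlation <= 1.0:
            raise ConfigurationError("trait_correlation must be in [-1, 1]")


def default_marker_map(n_markers: int, spacing_bp: int = 4000,
                       chromosome: str = "16") -> MarkerMap:
    """Evenly spaced SNP map (2-10 kb spacing is typical for fine-mapping)."""
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n_markers)]
    return MarkerMap(pd.DataFrame({
        "marker_id": [f"snp{j + 1:03d}" for j in range(n_markers)],
        "chromosome": chromosome,
        "position_bp": [100_000 + j * spacing_bp for j in range(n_markers)],
        "allele_a": [p[0] for p in pairs],
        "allele_b": [p[1] for p in pairs],
    }))


# ---------------------------------------------------------------------------
# Founder pool
# ---------------------------------------------------------------------------

def _block_partition(n_markers: int, n_blocks: int) -> list[tuple[int, int]]:
    sizes = np.full(n_blocks, n_markers // n_blocks, dtype=int)
    sizes[: n_markers % n_blocks] += 1
    bounds, start = [], 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return bounds


def build_founder_pool(markers: MarkerMap, n_blocks: int, haplos_per_block: int,
                       seed: int, maf_range: tuple[float, float] = (0.2, 0.5),
                       max_tries: int = 1000) -> FounderHaplotypePool:
    """Founder pool with ``n_blocks`` contiguous LD blocks.

    Within each block only ``haplos_per_block`` distinct strings exist, so
    every within-block marker pair is in strong LD; blocks combine with free
    recombination.  Block frequencies are mildly jittered around uniform and
    allele assignments are drawn so every marker's pool MAF falls in
    ``maf_range`` (lower bound exclusive, upper inclusive).
    """
    if n_blocks < 1:
        raise ConfigurationError("n_blocks must be >= 1")
    if markers.n_markers < n_blocks:
        raise ConfigurationError("fewer markers than blocks")
    rng = np.random.default_rng([seed, _STREAM_POOL])
    lo, hi = maf_range
    bounds = _block_partition(markers.n_markers, n_blocks)
    tab = markers.table
    k = haplos_per_block
    block_haps: list[list[str]] = []
    block_freqs: list[np.ndarray] = []
    for (start, stop) in bounds:
        blen = stop - start
        if k > 2 ** blen:
            raise ConfigurationError(
                f"block of {blen} markers cannot host {k} distinct haplotypes")
        for _ in range(max_tries):
            freqs = rng.dirichlet(np.full(k, 20.0))
            alleles = np.zeros((k, blen), dtype=np.int8)
            ok = True
            for j in range(blen):
                for _ in range(max_tries):
                    carriers = rng.random(k) < 0.5
                    p = float(freqs[carriers].sum())
                    maf = min(p, 1.0 - p)
                    if lo < maf <= hi:
                        alleles[:, j] = carriers
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            strings = []
            for i in range(k):
                s = "".join(
                    (tab.allele_b[start + j] if alleles[i, j] else tab.allele_a[start + j])
                    for j in range(blen))
                strings.append(s)
            if len(set(strings)) == k:
                block_haps.append(strings)
                block_freqs.append(freqs)
                break
        else:
            raise ConfigurationError(
                "could not realize requested block diversity within MAF bounds")
    # cross product across blocks = free recombination between blocks
    haplotypes, frequencies = [], []
    for combo in itertools.product(*(range(len(h)) for h in block_haps)):
        haplotypes.append("".join(block_haps[b][i] for b, i in enumerate(combo)))
        frequencies.append(float(np.prod([block_freqs[b][i] for b, i in enumerate(combo)])))
    return FounderHaplotypePool(
        markers=markers, haplotypes=haplotypes,
        frequencies=np.asarray(frequencies), block_boundaries=[b[0] for b in bounds])


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Genotypes plus the latent truth needed for Mendelian checks."""

    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame  # family_id, sample_id, sib_index (1/2)
    parental_haplotypes: np.ndarray = field(repr=False)  # (n_pairs, 4) pool idx
    child_haplotypes: np.ndarray = field(repr=False)     # (n_pairs, 2, 2) pool idx
    true_dosage: np.ndarray = field(repr=False)          # pre-missingness

    def sib_pairs(self) -> dict[str, tuple[str, str]]:
        out = {}
        for fam, sub in self.pedigree.groupby("family_id", sort=True):
            sids = sub.sort_values("sib_index")["sample_id"].tolist()
            out[fam] = (sids[0], sids[1])
        return out


def simulate_families(pool: FounderHaplotypePool, cfg: SimulationConfig) -> SimulatedCohort:
    """Draw sib pairs: 4 founder haplotypes per family, one transmitted per
    parent per child independently, no recombination within the locus."""
    rng = np.random.default_rng([cfg.seed, _STREAM_FAMILIES])
    n = cfg.n_pairs
    hap_dos = pool.dosage_matrix  # (H, M)
    parental = rng.choice(len(pool.haplotypes), size=(n, 4), p=pool.frequencies)
    # which of its two haplotypes each parent transmits, per child
    picks = rng.integers(0, 2, size=(n, 2, 2))  # (pair, child, parent)
    child_haps = np.empty((n, 2, 2), dtype=np.intp)
    child_haps[:, :, 0] = np.take_along_axis(
        parental[:, 0:2], picks[:, :, 0], axis=1)          # from parent 1
    child_haps[:, :, 1] = np.take_along_axis(
        parental[:, 2:4], picks[:, :, 1], axis=1)          # from parent 2
    true_dosage = (hap_dos[child_haps[:, :, 0]] + hap_dos[child_haps[:, :, 1]])
    true_dosage = true_dosage.reshape(2 * n, pool.markers.n_markers).astype(np.int8)
    dosage = true_dosage.copy()
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING
    fam_ids = [f"F{i + 1:04d}" for i in range(n)]
    sample_ids = [f"F{i + 1:04d}_S{c + 1}" for i in range(n) for c in range(2)]
    pedigree = pd.DataFrame({
        "family_id": np.repeat(fam_ids, 2),
        "sample_id": sample_ids,
        "sib_index": np.tile([1, 2], n),
    })
    ped6 = pd.DataFrame({
        "family_id": pedigree.family_id, "sample_id": pedigree.sample_id,
        "father": "0", "mother": "0", "sex": "0", "affection": "2"})
    gm = GenotypeMatrix(sample_ids, pool.markers, dosage, pedigree=ped6)
    return SimulatedCohort(genotypes=gm, pedigree=pedigree,
                           parental_haplotypes=parental,
                           child_haplotypes=child_haps, true_dosage=true_dosage)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def attach_phenotypes(cohort: SimulatedCohort, cfg: SimulationConfig,
                      birth_year_range: tuple[int, int] = (1960, 1995)) -> PhenotypeTable:
    """Two correlated severity traits with an additive causal decrement.

    latent_t = -effect_size * risk_dosage + pair_effect + noise_t, with the
    two traits' individual noises correlated at ``trait_correlation`` and the
    pair effect shared between sibs (and traits).  Latent traits are mapped
    to reported scales by their empirical cohort rank: fev1_centile on
    [0, 100], weight_pct_pred on a plausible [60, 130] band.  Higher values
    are milder on both scales.
    """
    markers = cohort.genotypes.markers
    try:
        cj = markers.index_of(cfg.causal_marker)
    except KeyError as exc:
        raise ConfigurationError(str(exc)) from exc
    rng = np.random.default_rng([cfg.seed, _STREAM_PHENO])
    n_samples = cohort.genotypes.n_samples
    n_pairs = n_samples // 2
    risk_dosage = cohort.true_dosage[:, cj].astype(float)
    pair_effect = np.repeat(rng.normal(0.0, cfg.family_effect_sd, n_pairs), 2)
    rho = cfg.trait_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    noise = rng.multivariate_normal([0.0, 0.0], cov, size=n_samples)
    latent = (-cfg.effect_size * risk_dosage)[:, None] + pair_effect[:, None] + noise
    # empirical rank transform; (rank - 0.5)/N lands strictly inside (0, 1)
    p_weight = (rankdata(latent[:, 0], method="average") - 0.5) / n_samples
    p_fev1 = (rankdata(latent[:, 1], method="average") - 0.5) / n_samples
    birth_year = rng.integers(birth_year_range[0], birth_year_range[1] + 1, n_samples)
    data = pd.DataFrame({
        "sample_id": cohort.genotypes.sample_ids,
        "family_id": cohort.pedigree["family_id"].to_numpy(),
        "weight_pct_pred": 60.0 + 70.0 * p_weight,
        "fev1_centile": 100.0 * p_fev1,
        "birth_year": birth_year,
    })
    return PhenotypeTable(data=data)


# ---------------------------------------------------------------------------
# Survivorship
# ---------------------------------------------------------------------------

def apply_survivorship(phenotypes: PhenotypeTable, genotypes: GenotypeMatrix,
                       cfg: SimulationConfig, cohort_split_year: int,
                       ) -> tuple[PhenotypeTable, GenotypeMatrix]:
    """Censor early-born patients by genotype before "enrollment".

    Patients born before ``cohort_split_year`` are retained with probability
    logistic(-survival_steepness * risk_dosage) at the causal marker; later
    births are always retained.  The returned cohort is the enrolled one, so
    cross-sectional recruitment bias is baked into all downstream counts.
    Missing causal genotypes count as dosage 0 (no penalty).
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_SURV])
    cj = genotypes.markers.index_of(cfg.causal_marker)
    ids = phenotypes.data["sample_id"].tolist()
    idx = genotypes.sample_index(ids)
    dosage = genotypes.dosage[idx, cj].astype(float)
    dosage[dosage == MISSING] = 0.0
    early = phenotypes.data["birth_year"].to_numpy() < cohort_split_year
    p_keep = 1.0 / (1.0 + np.exp(cfg.survival_steepness * dosage))
    keep = ~early | (rng.random(len(ids)) < p_keep)
    kept_ids = [s for s, k in zip(ids, keep) if k]
    pheno = PhenotypeTable(data=phenotypes.data.loc[keep].reset_index(drop=True),
                           rejects=list(phenotypes.rejects))
    return pheno, genotypes.subset_samples(kept_ids)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression_values(genotypes: GenotypeMatrix, index_marker: str,
                               per_allele_effect: float, noise_sd: float,
                               seed: int, baseline: float = 7.0) -> pd.DataFrame:
    """Expression = baseline + effect * benign-allele dosage + N(0, noise_sd).

    The benign allele is ``allele_a`` of the index marker.  Samples with a
    missing call at the index marker are dropped (they carry no genotype
    label).  Returns columns sample_id, genotype, expression.
    """
    a, b = genotypes.markers.alleles(index_marker)
    if b is None:
        raise ConfigurationError(f"index marker {index_marker} is monomorphic")
    rng = np.random.default_rng([seed, _STREAM_EXPR])
    j = genotypes.markers.index_of(index_marker)
    dos_b = genotypes.dosage[:, j]
    called = dos_b != MISSING
    benign_dosage = (2 - dos_b[called]).astype(float)
    expr = baseline + per_allele_effect * benign_dosage + rng.normal(0.0, noise_sd, called.sum())
    geno_str = {0: b + b, 1: a + b, 2: a + a}
    return pd.DataFrame({
        "sample_id": [s for s, c in zip(genotypes.sample_ids, called) if c],
        "genotype": [geno_str[int(d)] for d in benign_dosage],
        "expression": expr,
    })
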