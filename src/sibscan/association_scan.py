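"""Single-marker and 2-marker haplotype association scan with permutation
correction, fragment assignment and risk-allele annotation.

Two contrast designs are supported.  The *interpair* contrast compares two
disjoint groups of sibling pairs (e.g. concordant-mild vs concordant-severe
pairs); its exchangeable unit is the pair, so the permutation null reassigns
whole pairs between groups.  The *intrapair* contrast compares the mild with
the severe sibling within discordant pairs; its null is generated by
within-pair label swaps (each pair swapped independently with probability
1/2), which conditions on everything shared inside a pair.

Per window the test statistic is a likelihood-ratio comparing separate
haplotype-frequency fits of the two groups against the pooled fit
(2-marker windows) or the Pearson chi-square on the 2x2 allele table
(single markers).  Family-wise correction uses the min-p (max-statistic)
method: every permutation replicate re-tests the whole window family, each
window's statistics are converted to shared-pool Monte-Carlo p-values, and
Pcorr is the +1-corrected fraction of replicates whose minimum p undercuts
the observed minimum.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .haplotype_core import (N_CAT2, CAT2_ALL_MISSING, cat2_index, em2_batch,
                             em_haplotype_frequencies)
from .io_formats import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger("sibscan")

RARE_HAPLOTYPE_FREQ = 1e-6  # pooled-frequency floor for LRT df counting


class SpecificationError(ValueError):
    """Contrast or alignment specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSpec:
    """A two-group comparison.

    ``group_a`` is the mild side, ``group_b`` the severe side.  For
    intrapair mode ``pair_links`` lists (mild_sib, severe_sib) and must cover
    both groups.  For interpair mode ``families`` maps each sample to its
    pair id; pairs are the permutation unit.
    """

    name: str
    mode: str  # "interpair" | "intrapair"
    group_a: list[str]
    group_b: list[str]
    pair_links: list[tuple[str, str]] | None = None
    families: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("interpair", "intrapair"):
            raise SpecificationError(f"unknown contrast mode {self.mode!r}")
        if set(self.group_a) & set(self.group_b):
            raise SpecificationError("contrast groups must be disjoint")
        if self.mode == "intrapair":
            if not self.pair_links:
                raise SpecificationError("intrapair contrast needs pair_links")
            mild = [m for m, _ in self.pair_links]
            severe = [s for _, s in self.pair_links]
            if set(mild) != set(self.group_a) or set(severe) != set(self.group_b):
                raise SpecificationError(
                    "pair_links must cover group_a (mild) and group_b (severe) exactly")

    def units(self) -> list[tuple[list[str], list[str]]]:
        """Permutation units as (a_side_samples, b_side_samples) per unit.

        interpair: each unit is one pair, wholly on one side (the other side
        list is empty).  intrapair: each unit is one pair with its mild sib
        on the a side and its severe sib on the b side.
        """
        if self.mode == "intrapair":
            return [([m], [s]) for m, s in self.pair_links]
        fam = self.families or {s: s for s in self.group_a + self.group_b}
        units: dict[str, tuple[list[str], list[str]]] = {}
        for s in self.group_a:
            units.setdefault(fam.get(s, s), ([], []))[0].append(s)
        for s in self.group_b:
            units.setdefault(fam.get(s, s), ([], []))[1].append(s)
        for uid, (a, b) in units.items():
            if a and b:
                raise SpecificationError(
                    f"interpair unit {uid} has samples in both groups")
        return list(units.values())


def contrasts_from_classification(cls) -> tuple[ContrastSpec, ContrastSpec]:
    """Build the canonical interpair (CON+ vs CON-) and intrapair (DIS mild
    vs severe) contrasts from a :class:`~sibscan.phenotype_ranking.PairClassification`."""
    from .phenotype_ranking import LABEL_CON_MILD, LABEL_CON_SEVERE, LABEL_DIS
    families = {}
    families.update(cls.families_of(LABEL_CON_MILD))
    families.update(cls.families_of(LABEL_CON_SEVERE))
    interpair = ContrastSpec(
        name="interpair", mode="interpair",
        group_a=cls.members(LABEL_CON_MILD), group_b=cls.members(LABEL_CON_SEVERE),
        families=families)
    links = cls.pair_links(LABEL_DIS)
    intrapair = ContrastSpec(
        name="intrapair", mode="intrapair",
        group_a=[m for m, _ in links], group_b=[s for _, s in links],
        pair_links=links)
    return interpair, intrapair


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class WindowResult:
    window: tuple[str, ...]
    adjacent: bool          # True only for 2-marker windows of adjacent markers
    statistic: float
    praw: float
    df: int | None = None
    method: str = ""
    degenerate: bool = False


@dataclass
class ScanResult:
    contrast: ContrastSpec
    window_results: list[WindowResult]
    pbest: float
    pcorr: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    pbest_mc: float | None = None  # shared-pool MC min-p (set with pcorr)
    genotypes: GenotypeMatrix | None = field(default=None, repr=False)

    def praw_of(self, window: tuple[str, ...]) -> float:
        for w in self.window_results:
            if w.window == tuple(window):
                return w.praw
        raise KeyError(f"window {window} not in scan")


@dataclass
class FragmentCall:
    """Maximal run of consecutive significant adjacent windows."""

    fragment: tuple[str, str]
    supporting_windows: list[tuple[str, ...]]
    contrast: str


# ---------------------------------------------------------------------------
# Allele counting and chi-square
# ---------------------------------------------------------------------------

def _allele_counts(genotypes: GenotypeMatrix, samples, marker_id: str,
                   ) -> tuple[int, int]:
    """(allele_b count, total called alleles) in the sample set."""
    j = genotypes.markers.index_of(marker_id)
    col = genotypes.dosage[genotypes.sample_index(samples), j]
    called = col != MISSING
    return int(col[called].sum()), int(2 * called.sum())


def group_allele_freqs(genotypes: GenotypeMatrix, samples, marker_id: str,
                       ) -> dict[str, float]:
    """Observed allele frequencies in a sample group at one marker."""
    a, b = genotypes.markers.alleles(marker_id)
    nb, n = _allele_counts(genotypes, samples, marker_id)
    if n == 0:
        return {}
    out = {a: (n - nb) / n}
    if b is not None:
        out[b] = nb / n
    return out


def _chi2_2x2(nb_a, n_a, nb_b, n_b):
    """Vectorized Pearson chi-square on [[nb_a, n_a-nb_a], [nb_b, n_b-nb_b]].

    Returns 0 for any zero margin (degenerate table).
    """
    nb_a = np.asarray(nb_a, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    nb_b = np.asarray(nb_b, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    N = n_a + n_b
    c1 = nb_a + nb_b
    c2 = N - c1
    det = nb_a * (n_b - nb_b) - nb_b * (n_a - nb_a)
    denom = n_a * n_b * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, N * det * det / denom, 0.0)
    return stat


def single_marker_test(genotypes: GenotypeMatrix, contrast: ContrastSpec,
                       marker_id: str) -> WindowResult:
    """2x2 allele-count chi-square (1 df, no continuity correction)."""
    nb_a, n_a = _allele_counts(genotypes, contrast.group_a, marker_id)
    nb_b, n_b = _allele_counts(genotypes, contrast.group_b, marker_id)
    degenerate = False
    stat = float(_chi2_2x2(nb_a, n_a, nb_b, n_b))
    margins = [n_a, n_b, nb_a + nb_b, n_a + n_b - nb_a - nb_b]
    if min(margins) == 0:
        degenerate = True
        praw = 1.0
        stat = 0.0
    else:
        praw = float(chi2_dist.sf(stat, 1))
    return WindowResult(window=(marker_id,), adjacent=False, statistic=stat,
                        praw=praw, df=1, method="chi2-allele", degenerate=degenerate)


# ---------------------------------------------------------------------------
# Haplotype LRT (interpair)
# ---------------------------------------------------------------------------

def _lrt_components(genotypes, samples_a, samples_b, window, em_kwargs):
    pooled = em_haplotype_frequencies(
        genotypes.subset_samples(list(samples_a) + list(samples_b)), window,
        **em_kwargs)
    fit_a = em_haplotype_frequencies(genotypes.subset_samples(samples_a),
                                     window, **em_kwargs)
    fit_b = em_haplotype_frequencies(genotypes.subset_samples(samples_b),
                                     window, **em_kwargs)
    stat = max(2.0 * (fit_a.log_likelihood + fit_b.log_likelihood
                      - pooled.log_likelihood), 0.0)
    n_hap = int(np.sum(pooled.full_freqs > RARE_HAPLOTYPE_FREQ))
    df = max(n_hap - 1, 1)
    return stat, df, pooled


def haplotype_distribution_test(genotypes: GenotypeMatrix, contrast: ContrastSpec,
                                window, em_kwargs: dict | None = None,
                                ) -> WindowResult:
    """Likelihood-ratio comparison of group haplotype distributions.

    statistic = 2 [ll_A(A's MLE) + ll_B(B's MLE) - ll_pooled(pooled MLE)];
    asymptotic p on (H - 1) df where H counts haplotypes with pooled
    frequency above ``RARE_HAPLOTYPE_FREQ`` (rarer EM dust is pooled and does
    not inflate df).  The permutation engine supersedes this asymptotic value
    for family-wise claims.
    """
    em_kwargs = em_kwargs or {}
    stat, df, _ = _lrt_components(genotypes, contrast.group_a, contrast.group_b,
                                  list(window), em_kwargs)
    praw = float(chi2_dist.sf(stat, df))
    return WindowResult(window=tuple(window), adjacent=False, statistic=stat,
                        praw=praw, df=df, method="lrt-haplotype")


# ---------------------------------------------------------------------------
# Shared replicate engine
# ---------------------------------------------------------------------------

class _WindowEngine:
    """Per-window vectorized statistics over unit-level group assignments.

    Units come from ``ContrastSpec.units()``: each unit contributes an
    "a-side" and a "b-side" sample list.  An assignment row selects, per
    unit, whether the unit's sides are kept (0) or exchanged (1); for
    interpair units one side is empty, so exchanging a unit moves the whole
    pair across groups.
    """

    def __init__(self, genotypes: GenotypeMatrix, contrast: ContrastSpec,
                 windows: list[tuple[str, ...]]):
        self.windows = windows
        units = contrast.units()
        self.n_units = len(units)
        idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
        self.single_data = {}
        self.pair_data = {}
        for w in windows:
            if len(w) == 1:
                j = genotypes.markers.index_of(w[0])
                col = genotypes.dosage[:, j]

                def vec(samples, col=col):
                    v = np.zeros(2)
                    for s in samples:
                        d = col[idx[s]]
                        if d != MISSING:
                            v += (float(d), 2.0)
                    return v

                a_side = np.array([vec(a) for a, _ in units])
                b_side = np.array([vec(b) for _, b in units])
                self.single_data[w] = (a_side, b_side)
            elif len(w) == 2:
                j1 = genotypes.markers.index_of(w[0])
                j2 = genotypes.markers.index_of(w[1])
                cat = cat2_index(genotypes.dosage[:, j1], genotypes.dosage[:, j2])

                def catvec(samples, cat=cat):
                    v = np.zeros(N_CAT2)
                    for s in samples:
                        v[cat[idx[s]]] += 1.0
                    v[CAT2_ALL_MISSING] = 0.0
                    return v

                a_side = np.array([catvec(a) for a, _ in units])
                b_side = np.array([catvec(b) for _, b in units])
                self.pair_data[w] = (a_side, b_side)
            else:
                raise ValueError("engine supports windows of width 1 or 2")

    def statistics(self, swap: np.ndarray) -> np.ndarray:
        """(R, n_windows) statistics for R unit-exchange assignments."""
        swap = np.asarray(swap, dtype=float)
        R = swap.shape[0]
        out = np.empty((R, len(self.windows)))
        for k, w in enumerate(self.windows):
            if len(w) == 1:
                a_side, b_side = self.single_data[w]
                tot = a_side.sum(axis=0) + b_side.sum(axis=0)
                base = a_side.sum(axis=0)
                grp_a = base[None, :] + swap @ (b_side - a_side)
                nb_a, n_a = grp_a[:, 0], grp_a[:, 1]
                nb_b, n_b = tot[0] - nb_a, tot[1] - n_a
                out[:, k] = _chi2_2x2(nb_a, n_a, nb_b, n_b)
            else:
                a_side, b_side = self.pair_data[w]
                tot = a_side.sum(axis=0) + b_side.sum(axis=0)
                grp_a = a_side.sum(axis=0)[None, :] + swap @ (b_side - a_side)
                grp_b = tot[None, :] - grp_a
                _, ll_a = em2_batch(grp_a)
                _, ll_b = em2_batch(grp_b)
                _, ll_pool = em2_batch(tot[None, :])
                out[:, k] = np.maximum(2.0 * (ll_a + ll_b - ll_pool[0]), 0.0)
        return out


def _observed_swap(contrast: ContrastSpec, n_units: int) -> np.ndarray:
    return np.zeros((1, n_units))


def _replicate_swaps(contrast: ContrastSpec, n_units: int, R: int,
                     rng: np.random.Generator) -> np.ndarray:
    if contrast.mode == "intrapair":
        return rng.integers(0, 2, size=(R, n_units)).astype(float)
    # interpair: re-draw which units sit in group A, preserving its size
    units = contrast.units()
    obs_a = np.array([1.0 if a else 0.0 for a, _ in units])
    n_a = int(obs_a.sum())
    r = rng.random((R, n_units))
    kth = np.partition(r, n_a - 1, axis=1)[:, n_a - 1][:, None]
    new_a = (r <= kth).astype(float)
    # swap flag: unit changes side relative to the observed assignment
    return np.abs(new_a - obs_a[None, :])


# ---------------------------------------------------------------------------
# Intrapair test
# ---------------------------------------------------------------------------

def intrapair_haplotype_test(genotypes: GenotypeMatrix, contrast: ContrastSpec,
                             window, R: int = 2000, seed: int | None = None,
                             exhaustive: bool = False) -> WindowResult:
    """Within-pair label-swap test of the mild-vs-severe haplotype LRT.

    Monte-Carlo by default: each replicate independently swaps the
    mild/severe designation within each pair with probability 1/2 and
    Praw = (1 + #{replicate statistic >= observed}) / (R + 1).  With
    ``exhaustive=True`` all 2^n swap patterns are enumerated and the p-value
    is the exact proportion of patterns at or above the observed statistic
    (the identity pattern included).
    """
    if contrast.mode != "intrapair":
        raise SpecificationError("intrapair test requires an intrapair contrast")
    window = tuple(window)
    windows = [window]
    eng = _WindowEngine(genotypes, contrast, windows)
    obs = float(eng.statistics(_observed_swap(contrast, eng.n_units))[0, 0])
    if exhaustive:
        n = eng.n_units
        if n > 16:
            raise ValueError("exhaustive enumeration limited to 16 pairs")
        patterns = ((np.arange(1 << n)[:, None] >> np.arange(n)[None, :]) & 1)
        stats = eng.statistics(patterns.astype(float))[:, 0]
        praw = float(np.mean(stats >= obs - 1e-9))
        method = "swap-exhaustive"
    else:
        if R < 1:
            raise ValueError("R must be >= 1")
        rng = np.random.default_rng(seed)
        swaps = _replicate_swaps(contrast, eng.n_units, R, rng)
        stats = eng.statistics(swaps)[:, 0]
        praw = float((1 + np.sum(stats >= obs - 1e-9)) / (R + 1))
        method = "swap-mc"
    if len(window) == 1:
        df = 1
    else:
        pooled = em_haplotype_frequencies(
            genotypes.subset_samples(contrast.group_a + contrast.group_b),
            list(window))
        df = max(int(np.sum(pooled.full_freqs > RARE_HAPLOTYPE_FREQ)) - 1, 1)
    return WindowResult(window=window, adjacent=False, statistic=obs,
                        praw=praw, df=df, method=method)


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------

def _is_polymorphic(genotypes, samples, marker_id) -> bool:
    nb, n = _allele_counts(genotypes, samples, marker_id)
    return n > 0 and 0 < nb < n


def scan_windows(genotypes: GenotypeMatrix, contrast: ContrastSpec,
                 markers: list[str], include_nonadjacent: bool = False,
                 R: int = 2000, seed: int | None = None,
                 em_kwargs: dict | None = None) -> ScanResult:
    """Test all single markers and all adjacent (optionally all non-adjacent)
    2-marker windows over the informative marker list.

    Interpair contrasts use the asymptotic chi-square / LRT p-values as Praw;
    intrapair contrasts use the within-pair swap Monte-Carlo p (``R`` swaps,
    seeded).  Windows containing a marker monomorphic in the pooled groups
    are skipped and logged, never silently absorbed.  Pbest is the minimum
    Praw over the emitted family.
    """
    if len(markers) < 2:
        raise ValueError("scan needs at least 2 informative markers")
    order = {m: genotypes.markers.index_of(m) for m in markers}
    markers = sorted(markers, key=order.get)
    pooled_samples = contrast.group_a + contrast.group_b
    poly = {m: _is_polymorphic(genotypes, pooled_samples, m) for m in markers}
    for m, ok in poly.items():
        if not ok:
            logger.warning("scan: marker %s monomorphic in contrast %s, windows skipped",
                           m, contrast.name)
    windows: list[tuple[tuple[str, ...], bool]] = []
    windows += [((m,), False) for m in markers if poly[m]]
    adj = list(zip(markers, markers[1:]))
    windows += [((m1, m2), True) for m1, m2 in adj if poly[m1] and poly[m2]]
    if include_nonadjacent:
        for i, m1 in enumerate(markers):
            for m2 in markers[i + 2:]:
                if poly[m1] and poly[m2]:
                    windows.append(((m1, m2), False))
    results = []
    rng = np.random.default_rng(seed)
    for w, adjacent in windows:
        if contrast.mode == "interpair":
            if len(w) == 1:
                res = single_marker_test(genotypes, contrast, w[0])
            else:
                res = haplotype_distribution_test(genotypes, contrast, w, em_kwargs)
        else:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = intrapair_haplotype_test(genotypes, contrast, w, R=R, seed=sub_seed)
        res.adjacent = adjacent
        results.append(res)
    pbest = min(r.praw for r in results)
    return ScanResult(contrast=contrast, window_results=results, pbest=pbest,
                      seed=seed, genotypes=genotypes)


# ---------------------------------------------------------------------------
# Permutation correction (min-p / max-statistic)
# ---------------------------------------------------------------------------

def permutation_correct(scan: ScanResult, R: int, seed: int | None) -> ScanResult:
    """Family-wise correction by permutation of the exchangeable unit.

    Interpair: pair labels are reassigned between the two groups preserving
    group sizes.  Intrapair: within-pair swaps.  Every replicate re-tests
    the full window family; per-window statistics (observed and replicate)
    are converted to Monte-Carlo p-values against the shared replicate pool,
    and Pcorr = (1 + #{min-p_r <= min-p_observed}) / (R + 1).  The observed
    min-p is stored as ``pbest_mc``; by construction Pcorr >= pbest_mc and
    Pcorr >= 1/(R+1).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if scan.genotypes is None:
        raise ValueError("scan carries no genotypes; rerun scan_windows")
    contrast = scan.contrast
    windows = [w.window for w in scan.window_results]
    eng = _WindowEngine(scan.genotypes, contrast, windows)
    rng = np.random.default_rng(seed)
    obs_stats = eng.statistics(_observed_swap(contrast, eng.n_units))[0]
    swaps = _replicate_swaps(contrast, eng.n_units, R, rng)
    rep_stats = eng.statistics(swaps)  # (R, W)
    W = len(windows)
    rep_p = np.empty((R, W))
    obs_p = np.empty(W)
    for k in range(W):
        col = rep_stats[:, k]
        sorted_desc = np.sort(col)[::-1]
        # count of replicates with statistic >= value (ties included)
        def count_ge(vals):
            return len(col) - np.searchsorted(sorted_desc[::-1], vals, side="left")
        rep_p[:, k] = (1 + count_ge(col - 1e-9)) / (R + 1)
        obs_p[k] = (1 + count_ge(np.array([obs_stats[k] - 1e-9]))[0]) / (R + 1)
    minp_obs = float(obs_p.min())
    minp_rep = rep_p.min(axis=1)
    pcorr = float((1 + np.sum(minp_rep <= minp_obs + 1e-12)) / (R + 1))
    return dataclasses.replace(scan, pcorr=pcorr, n_permutations=R, seed=seed,
                               pbest_mc=minp_obs)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def assign_fragments(scan: ScanResult, alpha: float = 0.05) -> list[FragmentCall]:
    """Merge maximal runs of consecutive significant adjacent windows.

    Adjacent 2-marker windows with Praw < alpha are chained while each
    window's right marker is the next window's left marker; each chain
    becomes one fragment spanning the first window's start to the last
    window's end.  An empty list (no window below alpha) is a valid result.
    """
    adj = [w for w in scan.window_results if w.adjacent and len(w.window) == 2]
    if not adj:
        raise ValueError("scan contains no adjacent 2-marker windows")
    markers = scan.genotypes.markers if scan.genotypes is not None else None
    if markers is not None:
        adj.sort(key=lambda w: markers.index_of(w.window[0]))
    calls: list[FragmentCall] = []
    run: list[WindowResult] = []

    def flush():
        if run:
            calls.append(FragmentCall(
                fragment=(run[0].window[0], run[-1].window[1]),
                supporting_windows=[w.window for w in run],
                contrast=scan.contrast.name))

    for w in adj:
        if w.praw < alpha:
            if run and run[-1].window[1] != w.window[0]:
                flush()
                run = []
            run.append(w)
        else:
            flush()
            run = []
    flush()
    return calls


def consensus_fragment(calls_a: list[FragmentCall], calls_b: list[FragmentCall],
                       markers) -> list[tuple[str, str]]:
    """Pairwise marker-interval intersections of two fragment lists.

    Intervals are closed on both ends in marker-map order; empty
    intersections are dropped and duplicates collapsed.
    """
    out = []
    for fa in calls_a:
        sa, ea = markers.index_of(fa.fragment[0]), markers.index_of(fa.fragment[1])
        for fb in calls_b:
            sb, eb = markers.index_of(fb.fragment[0]), markers.index_of(fb.fragment[1])
            s, e = max(sa, sb), min(ea, eb)
            if s <= e:
                ids = markers.marker_ids
                iv = (ids[s], ids[e])
                if iv not in out:
                    out.append(iv)
    return out


def fragment_contains(markers, fragment: tuple[str, str], marker_id: str) -> bool:
    """Closed-interval membership in marker-map order."""
    s, e = markers.index_of(fragment[0]), markers.index_of(fragment[1])
    j = markers.index_of(marker_id)
    return s <= j <= e


# ---------------------------------------------------------------------------
# Consistent-difference filter & risk allele
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """One resequenced haplotype: its label, severity class and alleles."""

    haplotype_label: str
    severity_class: str  # "severe" | "mild"
    alleles: dict[str, str]


def consistent_difference_filter(alignment: list[HaplotypeAlignment],
                                 boundary: tuple[str, str] | None = None,
                                 ) -> list[str]:
    """Markers at which the two severity classes differ consistently.

    A marker qualifies when all severe-class haplotypes share one allele,
    all mild-class haplotypes share one allele, and the two alleles differ.
    ``boundary`` (closed, in alignment marker order) optionally restricts the
    scanned interval.
    """
    if not alignment:
        raise SpecificationError("empty alignment")
    marker_order = list(alignment[0].alleles.keys())
    for hap in alignment:
        if list(hap.alleles.keys()) != marker_order:
            missing = set(marker_order) ^ set(hap.alleles.keys())
            raise SpecificationError(
                f"haplotype {hap.haplotype_label}: marker set mismatch ({sorted(missing)})")
    severe = [h for h in alignment if h.severity_class == "severe"]
    mild = [h for h in alignment if h.severity_class == "mild"]
    if not severe or not mild:
        raise SpecificationError("need at least one haplotype in each severity class")
    if boundary is not None:
        try:
            i0 = marker_order.index(boundary[0])
            i1 = marker_order.index(boundary[1])
        except ValueError as exc:
            raise SpecificationError(f"boundary marker not in alignment: {exc}") from exc
        scan_markers = marker_order[min(i0, i1): max(i0, i1) + 1]
    else:
        scan_markers = marker_order
    out = []
    for m in scan_markers:
        sev_alleles = {h.alleles[m] for h in severe}
        mild_alleles = {h.alleles[m] for h in mild}
        if len(sev_alleles) == 1 and len(mild_alleles) == 1 and sev_alleles != mild_alleles:
            out.append(m)
    return out


@dataclass
class RiskAlleleCall:
    risk_allele: str | None
    consistent: bool
    votes: dict[str, str]   # contrast name -> risk vote
    ties: list[str]         # contrasts with an exact frequency tie


def annotate_risk_allele(freq_table: dict[str, dict[str, dict[str, float]]],
                         ) -> RiskAlleleCall:
    """Vote the risk allele across contrasts.

    ``freq_table`` maps contrast name -> {"mild": {allele: freq},
    "severe": {allele: freq}}.  Per contrast the allele more frequent in the
    severe group is the contrast's risk vote; an exact tie is flagged and
    excluded from the vote.  The overall call is the unanimous vote; the
    consistency flag is False on any disagreement or tie.
    """
    if not freq_table:
        raise ValidationError("empty frequency table")
    votes: dict[str, str] = {}
    ties: list[str] = []
    for name, groups in freq_table.items():
        for grp in ("mild", "severe"):
            if grp not in groups:
                raise ValidationError(f"contrast {name}: missing group {grp!r}")
            total = sum(groups[grp].values())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"contrast {name}: {grp} frequencies sum to {total}, not 1")
        sev = groups["severe"]
        best = max(sev.values())
        top = [a for a, f in sev.items() if f == best]
        if len(top) > 1:
            ties.append(name)
            continue
        votes[name] = top[0]
    distinct = set(votes.values())
    consistent = bool(votes) and len(distinct) == 1 and not ties
    risk = distinct.pop() if len(distinct) == 1 else None
    return RiskAlleleCall(risk_allele=risk, consistent=consistent,
                          votes=votes, ties=ties)
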