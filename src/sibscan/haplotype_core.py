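"""Haplotype-frequency EM, linkage disequilibrium, and block description.

The EM estimator treats each individual's unphased window genotype as a
mixture over the ordered haplotype pairs (h1, h2) compatible with it.  The
E-step weights each compatible pair by f(h1) f(h2) normalized over all
compatible pairs; the M-step sets f(h) proportional to the expected count of
h over 2N chromosomes.  Missing calls are handled by summing over both
alleles; individuals missing every call in a window are dropped from that
window's likelihood.  The log-likelihood is non-decreasing across iterations
(an EM guarantee that the tests assert explicitly).

Haplotypes within a window of width w are encoded as integers in
[0, 2**w): bit j (from the left-most marker) is 1 when the haplotype carries
``allele_b`` of marker j.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger("sibscan")

MAX_WINDOW = 12  # 2**12 haplotype states; the scan itself only uses width 2


class UndefinedLDError(ValueError):
    """LD statistics requested for a monomorphic marker."""


# ---------------------------------------------------------------------------
# Informative markers
# ---------------------------------------------------------------------------

def informative_markers(genotypes: GenotypeMatrix, maf_threshold: float) -> list[str]:
    """Markers whose observed MAF strictly exceeds the threshold, in map order.

    Missing calls are excluded from the denominator; markers with every call
    missing are excluded and reported in the log.
    """
    if not 0.0 <= maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5]")
    out = []
    for mid in genotypes.markers.marker_ids:
        maf = genotypes.minor_allele_frequency(mid)
        if maf != maf:  # NaN: all calls missing
            logger.warning("marker %s: all calls missing, excluded", mid)
            continue
        if maf > maf_threshold:
            out.append(mid)
    return out


# ---------------------------------------------------------------------------
# Genotype categories for a window
# ---------------------------------------------------------------------------

def _compatible_ordered_pairs(key: tuple[int, ...]) -> list[tuple[int, int]]:
    """All ordered haplotype pairs compatible with a window genotype key.

    key entries are per-marker dosages of allele_b (0/1/2) or MISSING.
    """
    per_marker = []
    for g in key:
        if g == 0:
            per_marker.append([(0, 0)])
        elif g == 2:
            per_marker.append([(1, 1)])
        elif g == 1:
            per_marker.append([(0, 1), (1, 0)])
        else:  # missing: both chromosomes free
            per_marker.append([(0, 0), (0, 1), (1, 0), (1, 1)])
    pairs = []
    for combo in itertools.product(*per_marker):
        h1 = h2 = 0
        for (b1, b2) in combo:
            h1 = (h1 << 1) | b1
            h2 = (h2 << 1) | b2
        pairs.append((h1, h2))
    return pairs


def window_categories(genotypes: GenotypeMatrix, window: list[str]):
    """Collapse samples to distinct window-genotype keys.

    Returns ``(keys, counts, cat_index, n_dropped)`` where cat_index maps each
    sample to its key index (or -1 when every call in the window is missing).
    """
    cols = [genotypes.markers.index_of(m) for m in window]
    sub = genotypes.dosage[:, cols]
    all_missing = (sub == MISSING).all(axis=1)
    keys_arr, inverse = np.unique(sub, axis=0, return_inverse=True)
    keys = [tuple(int(v) for v in k) for k in keys_arr]
    cat_index = inverse.astype(np.intp)
    cat_index[all_missing] = -1
    counts = np.bincount(cat_index[cat_index >= 0], minlength=len(keys)).astype(float)
    return keys, counts, cat_index, int(all_missing.sum())


# ---------------------------------------------------------------------------
# EM on collapsed category counts
# ---------------------------------------------------------------------------

def _em_on_counts(keys, counts, width, *, tol, max_iter, init_freqs,
                  track_ll=False):
    """EM over 2**width haplotype states given category counts.

    Returns (freqs, log_likelihood, n_iter, converged, ll_trace).
    """
    H = 1 << width
    pair_lists = [_compatible_ordered_pairs(k) for k in keys]
    h1s = [np.array([p[0] for p in pl], dtype=np.intp) for pl in pair_lists]
    h2s = [np.array([p[1] for p in pl], dtype=np.intp) for pl in pair_lists]
    n_chrom = 2.0 * counts.sum()
    if n_chrom == 0:
        raise ValueError("no informative individuals in window")
    f = np.asarray(init_freqs, dtype=float).copy()
    f /= f.sum()
    ll_trace = []
    converged = False
    it = 0
    ll = -np.inf
    for it in range(1, max_iter + 1):
        expected = np.zeros(H)
        ll = 0.0
        for c in range(len(keys)):
            if counts[c] == 0:
                continue
            w = f[h1s[c]] * f[h2s[c]]
            s = w.sum()
            if s <= 0:
                # category unreachable under current f: restart mass uniformly
                w = np.full(len(w), 1.0 / len(w))
                s = 1.0
                ll += counts[c] * np.log(1e-300)
            else:
                ll += counts[c] * np.log(s)
            w = (counts[c] / s) * w
            np.add.at(expected, h1s[c], w)
            np.add.at(expected, h2s[c], w)
        f_new = expected / n_chrom
        if track_ll:
            ll_trace.append(ll)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    # log-likelihood under the final frequencies
    ll = 0.0
    for c in range(len(keys)):
        if counts[c] == 0:
            continue
        s = float((f[h1s[c]] * f[h2s[c]]).sum())
        ll += counts[c] * np.log(max(s, 1e-300))
    if track_ll:
        ll_trace.append(ll)
    return f, ll, it, converged, ll_trace


@dataclass
class HaplotypeFrequencySet:
    """EM-estimated haplotype frequencies for one marker window."""

    window: list[str]
    haplotype_freqs: dict[str, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    marker_alleles: list[tuple[str, str | None]] = field(default_factory=list)
    full_freqs: np.ndarray | None = field(default=None, repr=False)
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def frequency(self, haplotype: str) -> float:
        return self.haplotype_freqs.get(haplotype, 0.0)


def _haplotype_string(h: int, width: int, alleles) -> str:
    chars = []
    for j in range(width):
        bit = (h >> (width - 1 - j)) & 1
        a, b = alleles[j]
        chars.append(str(b) if bit else a)
    return "".join(chars)


def em_haplotype_frequencies(genotypes: GenotypeMatrix, window: list[str],
                             tol: float = 1e-8, max_iter: int = 1000,
                             init: str = "uniform", seed: int | None = None,
                             n_restarts: int = 10, track_ll: bool = False,
                             ) -> HaplotypeFrequencySet:
    """Maximum-likelihood haplotype frequencies for ``window``.

    ``init='uniform'`` is deterministic; ``init='random'`` draws
    ``n_restarts`` Dirichlet starting points (seeded) and keeps the best
    final likelihood, guarding against local maxima on wide windows.
    Frequencies below 1e-12 are pruned from the reported mapping (the full
    vector stays available in ``full_freqs``).
    """
    if len(window) == 0:
        raise ValueError("empty marker window")
    if len(window) > MAX_WINDOW:
        raise ValueError(f"window wider than {MAX_WINDOW} markers not supported")
    width = len(window)
    keys, counts, _, n_dropped = window_categories(genotypes, window)
    if counts.sum() == 0:
        raise ValueError("every sample is missing all calls in the window")
    if n_dropped:
        logger.debug("window %s: dropped %d all-missing individuals",
                     window, n_dropped)
    H = 1 << width
    starts: list[np.ndarray] = []
    if init == "uniform":
        starts.append(np.full(H, 1.0 / H))
    elif init == "random":
        rng = np.random.default_rng(seed)
        for _ in range(max(1, n_restarts)):
            starts.append(rng.dirichlet(np.ones(H)))
    else:
        raise ValueError("init must be 'uniform' or 'random'")
    best = None
    for f0 in starts:
        res = _em_on_counts(keys, counts, width, tol=tol, max_iter=max_iter,
                            init_freqs=f0, track_ll=track_ll)
        if best is None or res[1] > best[1]:
            best = res
    f, ll, n_iter, converged, ll_trace = best
    alleles = [genotypes.markers.alleles(m) for m in window]
    freqs = {}
    for h in range(H):
        if f[h] >= 1e-12:
            freqs[_haplotype_string(h, width, alleles)] = float(f[h])
    return HaplotypeFrequencySet(
        window=list(window), haplotype_freqs=freqs, log_likelihood=float(ll),
        n_iterations=n_iter, converged=converged, marker_alleles=alleles,
        full_freqs=f, ll_trace=ll_trace)


# ---------------------------------------------------------------------------
# Fast 2-marker EM, vectorized over many samples of category counts
# (the permutation engine re-fits thousands of replicate groups per window)
# ---------------------------------------------------------------------------

# category index for a 2-marker key: (g1 + 1) * 4 + (g2 + 1), g in {-1,0,1,2}
N_CAT2 = 16
CAT2_ALL_MISSING = 0  # (-1, -1)

_PAIR_TABLE2 = []
for _g1 in (-1, 0, 1, 2):
    for _g2 in (-1, 0, 1, 2):
        _PAIR_TABLE2.append(_compatible_ordered_pairs((_g1, _g2)))


def cat2_index(dos1: np.ndarray, dos2: np.ndarray) -> np.ndarray:
    """Category index per sample for a 2-marker window (MISSING == -1)."""
    return (dos1.astype(np.intp) + 1) * 4 + (dos2.astype(np.intp) + 1)


def em2_batch(counts: np.ndarray, tol: float = 1e-8, max_iter: int = 500,
              ) -> tuple[np.ndarray, np.ndarray]:
    """EM for R independent 2-marker samples given as category counts.

    ``counts`` is (R, 16) over the cat2 categories; the all-missing category
    is ignored.  Returns ``(freqs (R, 4), log_likelihood (R,))``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    R = counts.shape[0]
    use = counts.copy()
    use[:, CAT2_ALL_MISSING] = 0.0
    n_chrom = 2.0 * use.sum(axis=1)
    if np.any(n_chrom == 0):
        raise ValueError("a replicate has no informative individuals")
    active = [c for c in range(N_CAT2) if use[:, c].any()]
    f = np.full((R, 4), 0.25)
    alive = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        expected = np.zeros((R, 4))
        for c in active:
            pairs = _PAIR_TABLE2[c]
            w = np.stack([f[:, h1] * f[:, h2] for (h1, h2) in pairs], axis=1)
            s = w.sum(axis=1)
            s = np.where(s <= 0, 1.0, s)
            w *= (use[:, c] / s)[:, None]
            for k, (h1, h2) in enumerate(pairs):
                expected[:, h1] += w[:, k]
                expected[:, h2] += w[:, k]
        f_new = expected / n_chrom[:, None]
        delta = np.abs(f_new - f).max(axis=1)
        f = f_new
        alive = delta >= tol
        if not alive.any():
            break
    ll = np.zeros(R)
    for c in active:
        pairs = _PAIR_TABLE2[c]
        s = np.zeros(R)
        for (h1, h2) in pairs:
            s += f[:, h1] * f[:, h2]
        ll += use[:, c] * np.log(np.maximum(s, 1e-300))
    return f, ll


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

@dataclass
class LDStats:
    """Pairwise linkage disequilibrium between two markers."""

    marker_pair: tuple[str, str]
    D: float
    D_prime: float
    r_squared: float


def ld_from_freqs(p_AB: float, p_Ab: float, p_aB: float, p_ab: float,
                  marker_pair: tuple[str, str] = ("m1", "m2")) -> LDStats:
    """LD statistics from the four 2-marker haplotype frequencies.

    Arguments are the frequencies of haplotypes (A,B), (A,b), (a,B), (a,b)
    where A/a are the two alleles of the first marker and B/b of the second.
    D = p(AB) - p(A)p(B); D' = |D| / Dmax with
    Dmax = min(p(A)p(b), p(a)p(B)) for D > 0 and min(p(A)p(B), p(a)p(b))
    for D < 0; r^2 = D^2 / (p(A)p(a)p(B)p(b)).  Both normalized statistics
    are clamped to [0, 1] against rounding.
    """
    pAB, pAb, paB, pab = p_AB, p_Ab, p_aB, p_ab
    total = pAB + pAb + paB + pab
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("haplotype frequencies must sum to 1")
    pA = pAB + pAb
    pa = 1.0 - pA
    pB = pAB + paB
    pb = 1.0 - pB
    if min(pA, pa) <= 0 or min(pB, pb) <= 0:
        raise UndefinedLDError("LD undefined for a monomorphic marker")
    D = pAB - pA * pB
    if D > 0:
        d_max = min(pA * pb, pa * pB)
    elif D < 0:
        d_max = min(pA * pB, pa * pb)
    else:
        d_max = 0.0
    d_prime = 0.0 if d_max == 0.0 else abs(D) / d_max
    r2 = D * D / (pA * pa * pB * pb)
    return LDStats(marker_pair=marker_pair, D=float(D),
                   D_prime=float(min(max(d_prime, 0.0), 1.0)),
                   r_squared=float(min(max(r2, 0.0), 1.0)))


def ld_pairwise(freqs: HaplotypeFrequencySet) -> LDStats:
    """LD statistics from an EM fit of a 2-marker window."""
    if len(freqs.window) != 2:
        raise ValueError("ld_pairwise needs a 2-marker window")
    f = freqs.full_freqs
    if f is None:
        alleles = freqs.marker_alleles
        f = np.zeros(4)
        for h in range(4):
            f[h] = freqs.frequency(_haplotype_string(h, 2, alleles))
    # integer encoding: bit order (m1, m2); A = allele_a
    pAB, pAb, paB, pab = f[0], f[1], f[2], f[3]
    return ld_from_freqs(pAB, pAb, paB, pab,
                         marker_pair=(freqs.window[0], freqs.window[1]))


# ---------------------------------------------------------------------------
# Haplotype blocks
# ---------------------------------------------------------------------------

def haplotype_blocks(genotypes: GenotypeMatrix, markers: list[str],
                     dprime_threshold: float = 0.8,
                     em_kwargs: dict | None = None) -> list[list[str]]:
    """Greedy left-to-right block extension on adjacent-pair D'.

    A block grows while the next adjacent marker pair has D' strictly above
    the threshold; blocks are maximal, non-overlapping and cover all markers
    (singletons allowed).  A pair with undefined LD (monomorphic marker)
    closes the block and is logged.
    """
    order = {m: genotypes.markers.index_of(m) for m in markers}
    if sorted(markers, key=order.get) != list(markers):
        raise ValueError("markers must be given in map order")
    em_kwargs = em_kwargs or {}
    blocks: list[list[str]] = []
    current = [markers[0]] if markers else []
    for left, right in zip(markers, markers[1:]):
        try:
            fit = em_haplotype_frequencies(genotypes, [left, right], **em_kwargs)
            stats = ld_pairwise(fit)
            extend = stats.D_prime > dprime_threshold
        except UndefinedLDError:
            logger.warning("pair (%s, %s): LD undefined, treated as block boundary",
                           left, right)
            extend = False
        if extend:
            current.append(right)
        else:
            blocks.append(current)
            current = [right]
    if current:
        blocks.append(current)
    return blocks
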