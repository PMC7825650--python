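"""Haplotype-frequency estimation, linkage disequilibrium, and block finding.

Haplotype frequencies at k biallelic loci are estimated from unphased
genotypes by the classic expectation–maximisation algorithm over the 2^k
possible haplotypes.  Pairwise LD (D, D', r²) is derived from the
two-locus EM fit, with a 90% likelihood-based confidence interval on D'.
Haplotype blocks follow the Gabriel confidence-interval rule with the
Haploview default thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import MISSING

__all__ = [
    "HaplotypeFrequencyEM",
    "em_haplotype_freqs",
    "LdResult",
    "pairwise_ld",
    "BlockThresholds",
    "HaplotypeBlock",
    "gabriel_blocks",
]


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype pairs (as bitmasks) consistent with one genotype.

    Bit j of a haplotype mask is the allele at locus j.  A genotype with h
    heterozygous loci admits 2^(h-1) distinct unordered pairs (1 if h=0).
    """
    het = [j for j, g in enumerate(geno) if g == 1]
    base = sum(1 << j for j, g in enumerate(geno) if g == 2)
    if not het:
        return [(base, base)]
    first, rest = het[0], het[1:]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for j, b in zip(rest, bits):
            if b:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((min(h1, h2), max(h1, h2)))
    return pairs


class HaplotypeFrequencyEM(BaseEstimator):
    """EM estimator of haplotype frequencies from unphased genotypes.

    The E-step distributes each ambiguous multilocus genotype over its
    consistent haplotype pairs in proportion to the current frequency
    products; the M-step re-estimates frequencies from the expected
    haplotype counts.  Frequencies are initialised at linkage-equilibrium
    products of the single-locus allele frequencies (deterministic — no
    random restarts).

    Parameters
    ----------
    tol
        Convergence threshold on the maximum absolute frequency change.
    max_iter
        Iteration cap; non-convergence is recorded, not raised.

    Attributes
    ----------
    haplotype_freqs_ : ndarray of shape (2**k,)
        Frequency of each haplotype, indexed by bitmask (bit j = locus j).
    frequencies_ : dict[tuple[int, ...], float]
        The same frequencies keyed by allele tuple in locus order.
    log_likelihoods_ : list of per-iteration log-likelihoods (non-decreasing).
    n_iter_, converged_ : EM bookkeeping.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n_subjects, k>=2 loci)")
        k = X.shape[1]
        if k > 16:
            raise ValueError("EM over 2^k haplotypes is limited to k <= 16")
        complete = X[(X != MISSING).all(axis=1)]
        if complete.shape[0] == 0:
            raise ValueError("no subject fully observed at all loci")
        patterns, counts = np.unique(complete, axis=0, return_counts=True)
        pair_sets = [_compatible_pairs(tuple(int(g) for g in p)) for p in patterns]

        # linkage-equilibrium initialisation
        p_alt = complete.mean(axis=0) / 2.0
        f = np.ones(2**k)
        for h in range(2**k):
            for j in range(k):
                f[h] *= p_alt[j] if (h >> j) & 1 else 1.0 - p_alt[j]
        f /= f.sum()

        n = complete.shape[0]
        loglik: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            expected = np.zeros(2**k)
            ll = 0.0
            for pairs, c in zip(pair_sets, counts):
                probs = np.array(
                    [(1.0 if h1 == h2 else 2.0) * f[h1] * f[h2] for h1, h2 in pairs]
                )
                tot = probs.sum()
                if tot <= 0.0:
                    # genotype unreachable under current f: spread uniformly
                    probs = np.ones(len(pairs))
                    tot = probs.sum()
                    ll += -np.inf
                else:
                    ll += c * np.log(tot)
                w = c * probs / tot
                for (h1, h2), wi in zip(pairs, w):
                    expected[h1] += wi
                    expected[h2] += wi
            loglik.append(float(ll))
            f_new = expected / (2.0 * n)
            delta = float(np.max(np.abs(f_new - f)))
            f = f_new
            if delta < self.tol:
                converged = True
                break

        self.n_loci_ = k
        self.n_obs_ = int(n)
        self.haplotype_freqs_ = f
        self.frequencies_ = {
            tuple((h >> j) & 1 for j in range(k)): float(f[h]) for h in range(2**k)
        }
        self.log_likelihoods_ = loglik
        self.n_iter_ = it
        self.converged_ = converged
        return self


def em_haplotype_freqs(
    genotypes, tol: float = 1e-8, max_iter: int = 1000
) -> dict[tuple[int, ...], float]:
    """Haplotype frequency map for unphased genotypes at k loci."""
    return HaplotypeFrequencyEM(tol=tol, max_iter=max_iter).fit(genotypes).frequencies_


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdResult:
    """Two-locus linkage disequilibrium summary.

    ``D`` is the raw haplotype-frequency covariance p_AB − p_A·p_B (for the
    alternative alleles), ``dprime`` its normalisation by the maximum
    attainable |D| given the allele frequencies, and ``r2`` the squared
    correlation.  ``dprime_ci`` is a 90% likelihood interval on |D'|.
    """

    d: float
    dprime: float
    r2: float
    dprime_ci: tuple[float, float]
    p_a: float
    p_b: float


def _genotype_pair_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    both = (ga != MISSING) & (gb != MISSING)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga[both] == i) & (gb[both] == j))
    return counts


def _dprime_ci(
    counts: np.ndarray, p_a: float, p_b: float, sign: float, d_max: float,
    grid: int = 201, lo_q: float = 0.05, hi_q: float = 0.95,
) -> tuple[float, float]:
    """90% CI on |D'| by a normalised-likelihood grid.

    Allele frequencies are held at their sample estimates; the multinomial
    likelihood of the 3x3 genotype table is evaluated on an even grid of
    D' in [0, 1] (D carrying the MLE sign), normalised to unit mass, and
    the cumulative 5% / 95% points are returned.  Deterministic by
    construction (no resampling).
    """
    ds = np.linspace(0.0, 1.0, grid)
    logl = np.full(grid, -np.inf)
    for i, dp in enumerate(ds):
        d = sign * dp * d_max
        p11 = p_a * p_b + d
        p10 = p_a * (1 - p_b) - d
        p01 = (1 - p_a) * p_b - d
        p00 = (1 - p_a) * (1 - p_b) + d
        hap = np.clip([p00, p01, p10, p11], 0.0, 1.0)
        p00, p01, p10, p11 = hap / hap.sum()
        probs = np.array(
            [
                [p00**2, 2 * p00 * p01, p01**2],
                [2 * p00 * p10, 2 * (p00 * p11 + p01 * p10), 2 * p01 * p11],
                [p10**2, 2 * p10 * p11, p11**2],
            ]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * np.log(probs)
        terms[counts == 0] = 0.0
        logl[i] = terms.sum()
    like = np.exp(logl - logl.max())
    cum = np.cumsum(like) / like.sum()
    lower = float(ds[int(np.searchsorted(cum, lo_q))])
    upper = float(ds[min(int(np.searchsorted(cum, hi_q)), grid - 1)])
    return lower, upper


def pairwise_ld(ga, gb, tol: float = 1e-8, max_iter: int = 1000) -> LdResult:
    """LD statistics between two biallelic loci from unphased genotypes.

    Haplotype frequencies come from the two-locus EM; D' uses the
    Lewontin normalisation D_max = min(p_A(1−p_B), (1−p_A)p_B) for D>0 and
    min(p_A·p_B, (1−p_A)(1−p_B)) for D<0.

    Raises
    ------
    ValueError
        If either locus is monomorphic among jointly observed subjects.
    """
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    both = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[both], gb[both]
    if ga.size == 0:
        raise ValueError("no subject observed at both loci")
    fa = ga.mean() / 2.0
    fb = gb.mean() / 2.0
    if fa in (0.0, 1.0) or fb in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")

    freqs = em_haplotype_freqs(np.column_stack([ga, gb]), tol=tol, max_iter=max_iter)
    p_a = freqs[(1, 0)] + freqs[(1, 1)]
    p_b = freqs[(0, 1)] + freqs[(1, 1)]
    d = freqs[(1, 1)] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d_max == 0 else min(abs(d) / d_max, 1.0)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom == 0 else min(d * d / denom, 1.0)

    counts = _genotype_pair_counts(ga, gb)
    sign = 1.0 if d >= 0 else -1.0
    ci = _dprime_ci(counts, p_a, p_b, sign, d_max if d_max > 0 else 1.0)
    return LdResult(
        d=float(d), dprime=float(dprime), r2=float(r2),
        dprime_ci=ci, p_a=float(p_a), p_b=float(p_b),
    )


# ---------------------------------------------------------------------------
# Gabriel confidence-interval blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockThresholds:
    """Gabriel-rule thresholds (Haploview defaults).

    A pair is *strong LD* when the D' CI upper bound is >= ``ci_upper_strong``
    and the lower bound >= ``ci_lower_strong``; *strong recombination* when
    the upper bound is < ``ci_upper_recomb``; anything else (including pairs
    involving a monomorphic locus) is uninformative.  A span of >= 2 variants
    is a block when at least ``informative_frac`` of its informative pairs
    are strong LD (and it has at least one informative pair).
    """

    ci_upper_strong: float = 0.98
    ci_lower_strong: float = 0.70
    ci_upper_recomb: float = 0.90
    informative_frac: float = 0.95


@dataclass
class HaplotypeBlock:
    """A contiguous run of variants in predominantly strong LD."""

    variant_indices: list[int]
    variant_ids: list[str]
    haplotypes: dict[tuple[int, ...], float] = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


def _pair_classes(genotypes: np.ndarray, thresholds: BlockThresholds) -> np.ndarray:
    """Classify each variant pair: +1 strong LD, -1 strong recomb, 0 uninformative."""
    m = genotypes.shape[1]
    cls = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                ld = pairwise_ld(genotypes[:, i], genotypes[:, j])
            except ValueError:
                continue
            lo, hi = ld.dprime_ci
            if hi >= thresholds.ci_upper_strong and lo >= thresholds.ci_lower_strong:
                cls[i, j] = cls[j, i] = 1
            elif hi < thresholds.ci_upper_recomb:
                cls[i, j] = cls[j, i] = -1
    return cls


def _span_is_block(cls: np.ndarray, i: int, j: int, frac: float) -> bool:
    sub = cls[i : j + 1, i : j + 1]
    iu = np.triu_indices(j - i + 1, k=1)
    vals = sub[iu]
    informative = np.count_nonzero(vals)
    if informative == 0:
        return False
    return (vals == 1).sum() / informative >= frac


def gabriel_blocks(
    genotypes,
    variant_ids: list[str] | None = None,
    thresholds: BlockThresholds | None = None,
    estimate_freqs: bool = True,
) -> list[HaplotypeBlock]:
    """Haplotype blocks by the Gabriel confidence-interval rule.

    Variants (columns of ``genotypes``) must be position-sorted.  All
    contiguous spans of >= 2 variants are scored; qualifying spans are
    accepted greedily, longest first (ties broken leftmost), discarding
    spans that overlap an accepted block.  Blocks are returned left to
    right with EM haplotype frequencies attached.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[1] < 2:
        raise ValueError("need a (subjects, >=2 variants) genotype matrix")
    m = genotypes.shape[1]
    if variant_ids is None:
        variant_ids = [f"var{j}" for j in range(m)]
    thr = thresholds or BlockThresholds()

    cls = _pair_classes(genotypes, thr)
    candidates = [
        (i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if _span_is_block(cls, i, j, thr.informative_frac)
    ]
    candidates.sort(key=lambda span: (-(span[1] - span[0]), span[0]))

    taken = np.zeros(m, dtype=bool)
    accepted: list[tuple[int, int]] = []
    for i, j in candidates:
        if not taken[i : j + 1].any():
            accepted.append((i, j))
            taken[i : j + 1] = True

    blocks = []
    for i, j in sorted(accepted):
        idx = list(range(i, j + 1))
        freqs: dict[tuple[int, ...], float] = {}
        if estimate_freqs:
            freqs = {
                h: f
                for h, f in em_haplotype_freqs(genotypes[:, idx]).items()
                if f > 1e-9
            }
        blocks.append(
            HaplotypeBlock(
                variant_indices=idx,
                variant_ids=[variant_ids[t] for t in idx],
                haplotypes=freqs,
            )
        )
    return blocks
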