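"""Variant-level QC and population-genetic statistics.

Implements the three standard array-QC rules — per-variant missingness,
minor-allele frequency, and a 1-df chi-squared Hardy–Weinberg test — as a
scikit-learn style column filter (:class:`GenotypeQC`) plus plain functions
for the individual statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import MISSING
from .genotypes import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "alt_allele_frequency",
    "hwe_chisq",
    "GenotypeQC",
    "qc_filter",
]


@dataclass(frozen=True)
class QcThresholds:
    """QC exclusion thresholds.

    A variant is excluded iff its missing rate is *greater than*
    ``max_missing_rate``, its MAF is *less than* ``min_maf``, or its HWE
    p-value is *less than* ``min_hwe_p`` — strict inequalities, so a
    variant sitting exactly on a threshold passes.
    """

    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def alt_allele_frequency(calls: np.ndarray) -> float:
    """Alternative-allele frequency of one variant.

    Missing calls are excluded from both numerator and denominator.

    Raises
    ------
    ValueError
        If every call is missing.
    """
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise ValueError("all calls missing; allele frequency undefined")
    return float(obs.sum()) / (2.0 * obs.size)


def hwe_chisq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """Chi-squared test (1 df) for departure from Hardy–Weinberg equilibrium.

    Expected genotype counts are taken from the observed allele frequency
    p̂: (n·p̂², 2n·p̂(1−p̂), n·(1−p̂)²); the statistic is Σ(O−E)²/E over the
    three genotype classes, without continuity correction.  A monomorphic
    variant is in trivial equilibrium: statistic 0, p-value 1.

    Returns
    -------
    (statistic, p_value)
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("need at least one genotyped subject")
    p = (2 * counts[2] + counts[1]) / (2 * n)  # alt-allele frequency
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Per-variant QC filter over a subjects x variants call matrix.

    Columns are dropped when they exceed the missingness threshold, fall
    below the MAF threshold, or fail the HWE test.  All three statistics
    are evaluated on the full input matrix (not recomputed after each
    removal), so the filter is idempotent.

    Parameters mirror :class:`QcThresholds`.

    Attributes
    ----------
    missing_rate_, maf_, hwe_p_ : ndarray of shape (n_variants,)
        Per-variant statistics.
    keep_mask_ : ndarray of bool
        True for variants that pass all three rules.
    reason_ : ndarray of object
        First failing rule per variant ('missingness', 'maf', 'hwe'),
        empty string for passing variants.
    """

    def __init__(
        self,
        max_missing_rate: float = 0.05,
        min_maf: float = 0.01,
        min_hwe_p: float = 1e-6,
    ):
        self.max_missing_rate = max_missing_rate
        self.min_maf = min_maf
        self.min_hwe_p = min_hwe_p

    def fit(self, X, y=None):
        QcThresholds(self.max_missing_rate, self.min_maf, self.min_hwe_p)
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("X must be a non-empty 2-D matrix")
        n_sub, n_var = X.shape
        miss = (X == MISSING).sum(axis=0) / n_sub
        freq = np.full(n_var, np.nan)
        hwe_p = np.full(n_var, np.nan)
        for j in range(n_var):
            col = X[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            freq[j] = obs.sum() / (2.0 * obs.size)
            _, hwe_p[j] = hwe_chisq(
                int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
            )
        maf = np.minimum(freq, 1.0 - freq)

        fail_miss = miss > self.max_missing_rate
        with np.errstate(invalid="ignore"):
            fail_maf = maf < self.min_maf
            fail_hwe = hwe_p < self.min_hwe_p
        # a fully missing variant has no defined MAF/HWE; it always fails
        fail_miss |= np.isnan(freq)

        reason = np.array([""] * n_var, dtype=object)
        reason[fail_hwe] = "hwe"
        reason[fail_maf] = "maf"
        reason[fail_miss] = "missingness"  # precedence: missingness > maf > hwe

        self.n_features_in_ = n_var
        self.missing_rate_ = miss
        self.alt_freq_ = freq
        self.maf_ = maf
        self.hwe_p_ = hwe_p
        self.keep_mask_ = ~(fail_miss | fail_maf | fail_hwe)
        self.reason_ = reason
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of variants than fit()")
        return X[:, self.keep_mask_]

    def report(self, rsids=None) -> pd.DataFrame:
        """Per-variant QC report (one row per input variant)."""
        if rsids is None:
            rsids = [f"var{j}" for j in range(self.n_features_in_)]
        return pd.DataFrame(
            {
                "rsid": list(rsids),
                "miss_rate": self.missing_rate_,
                "maf": self.maf_,
                "hwe_p": self.hwe_p_,
                "status": np.where(self.keep_mask_, "pass", "fail"),
                "reason": self.reason_,
            }
        )


def qc_filter(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply :class:`GenotypeQC` to a :class:`GenotypeMatrix`.

    Returns the filtered matrix and the per-variant QC report.
    """
    thr = thresholds or QcThresholds()
    qc = GenotypeQC(thr.max_missing_rate, thr.min_maf, thr.min_hwe_p).fit(matrix.calls)
    kept = [i for i in range(matrix.n_variants) if qc.keep_mask_[i]]
    return matrix.select_variants(kept), qc.report([v.rsid for v in matrix.variants])
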