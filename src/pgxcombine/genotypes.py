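"""Genotype containers: variant records and the subjects x variants call matrix.

Calls are coded as alternative-allele counts {0, 1, 2}; ``-1`` marks a
missing call.  Positions are 1-based hg19 throughout the in-memory model;
0-based half-open coordinates exist only at the BED I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._utils import MISSING

__all__ = ["VariantRecord", "GenotypeMatrix", "MISSING"]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV on the forward strand of hg19."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes for a cohort.

    Parameters
    ----------
    subjects
        Ordered subject identifiers.
    variants
        Ordered :class:`VariantRecord` list (one per column of ``calls``).
    calls
        ``(n_subjects, n_variants)`` integer array with values in
        ``{0, 1, 2, -1}`` (-1 = missing).
    """

    subjects: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, -1}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, rsid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.rsid == rsid:
                return i
        raise KeyError(f"variant {rsid!r} not in matrix")

    def column(self, rsid: str) -> np.ndarray:
        """Calls for one variant across all subjects."""
        return self.calls[:, self.variant_index(rsid)]

    def select_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )
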