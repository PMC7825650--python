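"""Gene regions and flank padding.

Pharmacogene analyses conventionally extend each gene's span by a flank on
both sides so that promoter/UTR variants and CNV breakpoints just outside
the annotated body still count toward the gene.  The default flank is
10 kb on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["GeneRegion", "pad_gene_region", "DEFAULT_PAD"]

DEFAULT_PAD = 10_000


@dataclass(frozen=True)
class GeneRegion:
    """A gene span in 1-based inclusive hg19 coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    pad: int = DEFAULT_PAD

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene}: start must be >= 1")
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.pad < 0:
            raise ValueError(f"{self.gene}: pad must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end] (1-based inclusive) intersects this region by >= 1 bp."""
        return chrom == self.chrom and start <= self.end and end >= self.start


def pad_gene_region(region: GeneRegion) -> GeneRegion:
    """Extend a region by its flank on both sides, clamping the start at 1.

    Strand-independent: the same pad is applied upstream and downstream.
    The returned region has ``pad=0`` so that padding is not applied twice.
    """
    return replace(
        region,
        start=max(1, region.start - region.pad),
        end=region.end + region.pad,
        pad=0,
    )
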