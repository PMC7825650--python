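"""Joint SNV x CNV reporting: combined categories, frequency tables, and
the end-to-end pipeline driver.

Each subject contributes exactly one combined category per gene: the
star-allele diplotype label, suffixed with " gain" or " loss" according
to the gene-level CNV *summary* status (amplification folds into gain
and deletion into loss for labelling; copy-neutral subjects get no
suffix).  Per gene, category counts therefore sum to the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._utils import round_half_up
from .cnv import (
    ClassifierThresholds,
    CnvStatus,
    ProbeSeries,
    SegmentationParams,
    classify_segment,
    cnv_frequency_table,
    filter_regions,
    gene_cnv_status,
    segment_series,
)
from .genotypes import GenotypeMatrix
from .regions import GeneRegion, pad_gene_region
from .snv import QcThresholds, qc_filter
from .star import Diplotype, StarAlleleCaller, StarAlleleDefinitions

__all__ = [
    "CombinedCategory",
    "FrequencyTable",
    "combine",
    "tabulate",
    "PipelineResult",
    "run_pipeline",
]

_SUFFIX = {
    CnvStatus.NEUTRAL: "",
    CnvStatus.GAIN: " gain",
    CnvStatus.AMPLIFICATION: " gain",
    CnvStatus.LOSS: " loss",
    CnvStatus.DELETION: " loss",
}


@dataclass(frozen=True)
class CombinedCategory:
    """One subject's combined diplotype + CNV category at one gene."""

    gene: str
    diplotype: str
    suffix: str  # "", " gain" or " loss"

    @property
    def label(self) -> str:
        return self.diplotype + self.suffix


def combine(diplotype: Diplotype, status: CnvStatus, gene: str | None = None) -> CombinedCategory:
    """Merge a diplotype with the gene-level CNV summary status.

    ``gene``, if given, must match the diplotype's gene (guards against
    joining rows from different genes).
    """
    if gene is not None and gene != diplotype.gene:
        raise ValueError(f"gene mismatch: {gene!r} vs {diplotype.gene!r}")
    return CombinedCategory(
        gene=diplotype.gene, diplotype=diplotype.label, suffix=_SUFFIX[status]
    )


@dataclass
class FrequencyTable:
    """Category counts and half-up-rounded percentages for one cohort."""

    rows: pd.DataFrame  # columns: gene, category, count, percent
    n: int

    def gene_rows(self, gene: str) -> pd.DataFrame:
        return self.rows[self.rows["gene"] == gene].reset_index(drop=True)

    def percent(self, gene: str, category: str) -> float:
        sel = self.rows[(self.rows["gene"] == gene) & (self.rows["category"] == category)]
        if sel.empty:
            return 0.0
        return float(sel["percent"].iloc[0])

    def count(self, gene: str, category: str) -> int:
        sel = self.rows[(self.rows["gene"] == gene) & (self.rows["category"] == category)]
        if sel.empty:
            return 0
        return int(sel["count"].iloc[0])


def tabulate(categories: Sequence[CombinedCategory], n: int) -> FrequencyTable:
    """Count combined categories across the cohort.

    Every subject must contribute exactly one category per gene, so the
    per-gene counts sum to ``n``.  Rows are ordered by gene, then by
    descending count, then by label.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    counts: dict[tuple[str, str], int] = {}
    for cat in categories:
        key = (cat.gene, cat.label)
        counts[key] = counts.get(key, 0) + 1
    for gene in {g for g, _ in counts}:
        total = sum(c for (g, _), c in counts.items() if g == gene)
        if total != n:
            raise ValueError(f"{gene}: categories cover {total} subjects, expected {n}")
    rows = pd.DataFrame(
        [
            {
                "gene": gene,
                "category": label,
                "count": count,
                "percent": round_half_up(100.0 * count / n),
            }
            for (gene, label), count in counts.items()
        ]
    ).sort_values(
        ["gene", "count", "category"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return FrequencyTable(rows=rows, n=n)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    per_subject: pd.DataFrame      # subject, gene, diplotype, resolved, cnv_summary, category
    combined: FrequencyTable       # combined diplotype x CNV table
    gene_cnv: pd.DataFrame         # per-gene gain/loss frequency table
    qc_report: pd.DataFrame | None
    segments: pd.DataFrame         # filtered, classified segments per subject


def run_pipeline(
    genotypes: GenotypeMatrix,
    probe_tracks: Mapping[str, Sequence[ProbeSeries]],
    regions: Sequence[GeneRegion],
    definitions: StarAlleleDefinitions,
    seg_params: SegmentationParams | None = None,
    cls_thresholds: ClassifierThresholds | None = None,
    qc_thresholds: QcThresholds | None = None,
    apply_qc: bool = True,
) -> PipelineResult:
    """Run the full combined analysis.

    Stages: variant QC; per-subject, per-chromosome segmentation of the
    probe tracks; segment classification and the >50 bp non-neutral
    filter; gene-level status against the +/-10 kb padded regions;
    star-allele diplotyping; combined category tabulation.
    """
    seg_params = seg_params or SegmentationParams()
    cls = cls_thresholds or ClassifierThresholds()

    qc_report = None
    if apply_qc:
        genotypes, qc_report = qc_filter(genotypes, qc_thresholds)

    padded = {r.gene: pad_gene_region(r) for r in regions}
    n = genotypes.n_subjects

    seg_rows = []
    summary: dict[str, list[CnvStatus]] = {r.gene: [] for r in regions}
    status_sets: dict[str, list[set[CnvStatus]]] = {r.gene: [] for r in regions}
    for sid in genotypes.subjects:
        kept: list = []
        for series in probe_tracks.get(sid, []):
            segments = [
                classify_segment(s, cls) for s in segment_series(series, seg_params)
            ]
            kept.extend(filter_regions(segments, cls))
        for seg in kept:
            seg_rows.append(
                {
                    "subject": sid,
                    "chrom": seg.chrom,
                    "start": seg.start_pos,
                    "end": seg.end_pos,
                    "n_probes": seg.n_probes,
                    "mean_log2": seg.mean_log2,
                    "status": seg.status.value,
                }
            )
        for gene, region in padded.items():
            sts, summ = gene_cnv_status(kept, region)
            status_sets[gene].append(sts)
            summary[gene].append(summ)

    caller = StarAlleleCaller(definitions).fit()
    per_subject_rows = []
    categories: list[CombinedCategory] = []
    for gene in padded:
        diplotypes = caller.call_matrix(genotypes, gene)
        for i, sid in enumerate(genotypes.subjects):
            cat = combine(diplotypes[i], summary[gene][i])
            categories.append(cat)
            per_subject_rows.append(
                {
                    "subject": sid,
                    "gene": gene,
                    "diplotype": diplotypes[i].label,
                    "resolved": diplotypes[i].resolved,
                    "cnv_summary": summary[gene][i].value,
                    "category": cat.label,
                }
            )

    return PipelineResult(
        per_subject=pd.DataFrame(per_subject_rows),
        combined=tabulate(categories, n),
        gene_cnv=cnv_frequency_table(status_sets, n),
        qc_report=qc_report,
        segments=pd.DataFrame(
            seg_rows,
            columns=["subject", "chrom", "start", "end", "n_probes", "mean_log2", "status"],
        ),
    )
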