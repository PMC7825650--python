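"""File-format boundaries: VCF, probe TSV, BED, and definition tables.

On-disk conventions: VCFv4.2 with a GT-only FORMAT and unphased "0/1"
coding ("./." = missing); probe tracks as 3-column TSV (chrom, pos,
log2ratio) with one file per subject; gene regions as BED (0-based
half-open on disk, 1-based inclusive in memory).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import MISSING
from .cnv import ProbeSeries
from .genotypes import GenotypeMatrix, VariantRecord
from .regions import GeneRegion

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_probe_tsv",
    "read_probe_tsv",
    "write_bed",
    "read_bed",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal uncompressed VCFv4.2 (GT field only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxcombine\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.subjects)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            gts = "\t".join(_GT_CODE[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Uses cyvcf2 when available, falling back to a plain-text reader for
    the minimal GT-only files this package writes.  Multi-allelic or
    non-SNV records are rejected.
    """
    try:
        import cyvcf2
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        return _read_vcf_text(path)

    vcf = cyvcf2.VCF(str(path))
    subjects = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(f"{rec.ID or rec.POS}: only biallelic SNVs are supported")
        variants.append(
            VariantRecord(
                rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        types = rec.gt_types
        col = np.select(
            [types == 0, types == 1, types == 3], [0, 1, 2], default=MISSING
        )
        columns.append(col.astype(np.int8))
    vcf.close()
    if not variants:
        raise ValueError(f"{path}: no variants")
    return GenotypeMatrix(subjects, variants, np.column_stack(columns))


def _read_vcf_text(path: str | Path) -> GenotypeMatrix:
    subjects: list[str] = []
    variants: list[VariantRecord] = []
    columns = []
    decode = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING,
              "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": MISSING}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                subjects = fields[9:]
                continue
            chrom, pos, rsid, ref, alt = fields[:5]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"{rsid}: only biallelic SNVs are supported")
            variants.append(VariantRecord(rsid, chrom, int(pos), ref, alt))
            columns.append(
                np.array(
                    [decode[g.split(":")[0]] for g in fields[9:]], dtype=np.int8
                )
            )
    if not variants:
        raise ValueError(f"{path}: no variants")
    return GenotypeMatrix(subjects, variants, np.column_stack(columns))


def write_probe_tsv(series_list: Iterable[ProbeSeries], path: str | Path) -> None:
    """Write one subject's probe tracks (all chromosomes) to a 3-column TSV."""
    frames = [
        pd.DataFrame(
            {"chrom": s.chrom, "pos": s.positions, "log2ratio": s.log2r}
        )
        for s in series_list
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_probe_tsv(path: str | Path, subject: str | None = None) -> list[ProbeSeries]:
    """Read a per-subject probe TSV, one :class:`ProbeSeries` per chromosome."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "log2ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: probe TSV needs columns {sorted(required)}")
    sid = subject if subject is not None else path.stem
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        out.append(
            ProbeSeries(
                subject=sid,
                chrom=str(chrom),
                positions=grp["pos"].to_numpy(),
                log2r=grp["log2ratio"].to_numpy(),
            )
        )
    return out


def write_bed(regions: Sequence[GeneRegion], path: str | Path) -> None:
    """Write gene regions as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\n")


def read_bed(path: str | Path, pad: int = 10_000) -> list[GeneRegion]:
    """Read a 4-column BED into 1-based inclusive :class:`GeneRegion` objects."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene = line.split("\t")[:4]
            out.append(
                GeneRegion(gene=gene, chrom=chrom, start=int(start) + 1,
                           end=int(end), pad=pad)
            )
    if not out:
        raise ValueError(f"{path}: no regions")
    return out
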