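"""Table-driven star-allele diplotype assignment from unphased genotypes.

A star allele is a named haplotype of a pharmacogene defined by the
alternative alleles it carries at one or more defining SNVs; *1 is the
all-reference haplotype.  Given a subject's unphased genotype at a
gene's defining SNVs, every haplotype pair consistent with the genotype
is enumerated; when exactly one pair consists of named alleles the
diplotype is reported as that canonical pair.  Genotypes whose only
consistent phasings involve an unnamed haplotype (one carrying the
defining variants of more than one named allele) are reported with an
explicit per-locus composite label and flagged unresolved rather than
forced into a canonical call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import MISSING, star_sort_key
from .genotypes import GenotypeMatrix

__all__ = [
    "StarAllele",
    "StarAlleleDefinitions",
    "Diplotype",
    "assign_diplotype",
    "StarAlleleCaller",
    "load_definitions",
    "default_definitions",
]


@dataclass(frozen=True)
class StarAllele:
    """A named star allele and the alt alleles that define it."""

    gene: str
    name: str  # e.g. "*3C"
    defining: tuple[tuple[str, str], ...]  # ((rsid, alt), ...) in table order


class StarAlleleDefinitions:
    """Star-allele definition tables for one or more genes.

    The reference allele *1 is implicit (empty defining set).  Within a
    gene, allele order follows first appearance in the table; composite
    ambiguity labels are rendered in that order.
    """

    def __init__(self, alleles: Sequence[StarAllele]):
        self._by_gene: dict[str, list[StarAllele]] = {}
        for a in alleles:
            self._by_gene.setdefault(a.gene, []).append(a)
        for gene, allele_list in self._by_gene.items():
            seen = set()
            for a in allele_list:
                key = frozenset(a.defining)
                if not a.defining:
                    raise ValueError(f"{gene} {a.name}: empty defining set is reserved for *1")
                if key in seen:
                    raise ValueError(f"{gene}: duplicate defining set for {a.name}")
                seen.add(key)

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def alleles(self, gene: str) -> list[StarAllele]:
        try:
            return self._by_gene[gene]
        except KeyError:
            raise KeyError(f"no star-allele definitions for gene {gene!r}") from None

    def defining_rsids(self, gene: str) -> list[str]:
        """All defining SNVs of a gene, deduplicated, in table order."""
        out: list[str] = []
        for a in self.alleles(gene):
            for rsid, _ in a.defining:
                if rsid not in out:
                    out.append(rsid)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": a.gene, "allele": a.name, "rsid": rsid, "alt": alt}
            for allele_list in self._by_gene.values()
            for a in allele_list
            for rsid, alt in a.defining
        ]
        return pd.DataFrame(rows, columns=["gene", "allele", "rsid", "alt"])


@dataclass(frozen=True)
class Diplotype:
    """The star-allele pair carried by one subject at one gene.

    ``label`` is either a canonical pair such as ``*1*3`` (allele names in
    ascending star order) or, when phase cannot be resolved into named
    alleles, a composite per-locus label such as ``*1*2-*3*3`` with
    ``resolved`` False.
    """

    gene: str
    label: str
    resolved: bool


def _composite_label(
    ordered_alleles: Sequence[StarAllele], genotypes: Mapping[str, int]
) -> str:
    parts: list[str] = []
    for allele in ordered_alleles:
        for rsid, _ in allele.defining:
            g = genotypes[rsid]
            if g == 1:
                part = f"*1{allele.name}"
            elif g == 2:
                part = f"{allele.name}{allele.name}"
            else:
                continue
            if not parts or parts[-1] != part:
                parts.append(part)
    return "-".join(parts)


def assign_diplotype(
    gene: str,
    genotypes: Mapping[str, int],
    definitions: StarAlleleDefinitions,
) -> Diplotype:
    """Assign a star-allele diplotype from unphased defining-SNV genotypes.

    Parameters
    ----------
    genotypes
        rsid -> alt-allele count (0/1/2) at every defining SNV of the gene.

    Notes
    -----
    A double heterozygote across two single-SNV alleles resolves to the
    trans pair (the cis phasing would require an unnamed haplotype, so the
    trans named pair is the unique named-pair explanation).
    """
    alleles = definitions.alleles(gene)
    rsids = definitions.defining_rsids(gene)
    for rsid in rsids:
        if rsid not in genotypes or genotypes[rsid] == MISSING:
            raise ValueError(f"{gene}: missing genotype at defining SNV {rsid}")
        if genotypes[rsid] not in (0, 1, 2):
            raise ValueError(f"{gene}: invalid genotype at {rsid}")

    locus_of = {rsid: j for j, rsid in enumerate(rsids)}
    named: dict[frozenset[int], str] = {frozenset(): "*1"}
    for a in alleles:
        named[frozenset(locus_of[r] for r, _ in a.defining)] = a.name

    geno_vec = tuple(genotypes[r] for r in rsids)
    het = [j for j, g in enumerate(geno_vec) if g == 1]
    base = frozenset(j for j, g in enumerate(geno_vec) if g == 2)

    named_pairs: set[tuple[str, str]] = set()
    if not het:
        if base in named:
            named_pairs.add((named[base], named[base]))
    else:
        first, rest = het[0], het[1:]
        for bits in itertools.product((0, 1), repeat=len(rest)):
            h1 = set(base) | {first}
            h2 = set(base)
            for j, b in zip(rest, bits):
                (h1 if b else h2).add(j)
            n1 = named.get(frozenset(h1))
            n2 = named.get(frozenset(h2))
            if n1 is not None and n2 is not None:
                pair = tuple(sorted((n1, n2), key=star_sort_key))
                named_pairs.add(pair)  # type: ignore[arg-type]

    if len(named_pairs) == 1:
        a1, a2 = next(iter(named_pairs))
        return Diplotype(gene=gene, label=f"{a1}{a2}", resolved=True)
    return Diplotype(
        gene=gene, label=_composite_label(alleles, genotypes), resolved=False
    )


class StarAlleleCaller(BaseEstimator):
    """Scikit-learn style wrapper around :func:`assign_diplotype`.

    The definition table is the 'model'; ``fit`` only validates it.
    ``predict`` maps a (subjects x defining-SNVs) genotype matrix to
    diplotype labels.
    """

    def __init__(self, definitions: StarAlleleDefinitions | None = None):
        self.definitions = definitions

    def fit(self, X=None, y=None):
        self.definitions_ = self.definitions or default_definitions()
        return self

    def _defs(self) -> StarAlleleDefinitions:
        if not hasattr(self, "definitions_"):
            self.fit()
        return self.definitions_

    def predict(self, X, gene: str, rsids: Sequence[str] | None = None) -> np.ndarray:
        """Diplotype labels for each row of X (columns = defining SNVs)."""
        defs = self._defs()
        rsids = list(rsids) if rsids is not None else defs.defining_rsids(gene)
        X = np.asarray(X)
        labels = [
            assign_diplotype(gene, dict(zip(rsids, map(int, row))), defs).label
            for row in X
        ]
        return np.array(labels, dtype=object)

    def call_matrix(self, matrix: GenotypeMatrix, gene: str) -> list[Diplotype]:
        """Diplotypes for every subject of a genotype matrix."""
        defs = self._defs()
        rsids = defs.defining_rsids(gene)
        cols = {r: matrix.column(r) for r in rsids}
        return [
            assign_diplotype(
                gene, {r: int(cols[r][i]) for r in rsids}, defs
            )
            for i in range(matrix.n_subjects)
        ]


def load_definitions(path: str | Path) -> StarAlleleDefinitions:
    """Read a star-allele definition TSV (columns gene, allele, rsid, alt)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "allele", "rsid", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"definition table needs columns {sorted(required)}")
    alleles = []
    for (gene, name), grp in df.groupby(["gene", "allele"], sort=False):
        alleles.append(
            StarAllele(
                gene=gene,
                name=name,
                defining=tuple(zip(grp["rsid"], grp["alt"])),
            )
        )
    return StarAlleleDefinitions(alleles)


def default_definitions() -> StarAlleleDefinitions:
    """The definition table shipped with the package.

    Covers CYP4F2 *2/*3, TPMT *3C, CYP2C19 *2/*3 and CYP3A5 *3; the TSV
    under ``pgxcombine/data`` is editable/extensible by users.
    """
    with resources.as_file(
        resources.files("pgxcombine").joinpath("data/star_alleles.tsv")
    ) as p:
        return load_definitions(p)
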