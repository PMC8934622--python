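"""HPO-driven gene ranking integration and trio segregation filters.

Consumes a gene -> Z-score table (the output format of HPO-profile gene
prioritizers, where higher Z means a stronger predicted phenotype link),
converts Z-scores to mid-rank percentiles over all table genes, filters
annotated variants by evidence level and gene percentile, and applies
trio inheritance filters: recessive/dominant segregation and
compound-heterozygote pairing with parental-genotype trans inference.

Percentile presets follow common usage: 0.90 (permissive gating), 0.95
(likely disease-related) and 0.99 (strongly disease-related).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PERCENTILE_PRESETS = {"permissive": 0.90, "likely": 0.95, "strong": 0.99}

Genotype = tuple[int, ...]


# ---------------------------------------------------------------------------
# Gene rank table


class GeneRankTable:
    """Gene -> Z-score table with derived mid-rank percentiles."""

    def __init__(self, zscores: Mapping[str, float]):
        if not zscores:
            raise ValueError("empty gene rank table")
        self.zscores = dict(zscores)
        z = np.array(list(self.zscores.values()), dtype=float)
        order = np.sort(z)
        n = len(z)
        self._percentiles = {}
        for gene, zi in self.zscores.items():
            less = np.searchsorted(order, zi, side="left")
            leq = np.searchsorted(order, zi, side="right")
            self._percentiles[gene] = (less + 0.5 * (leq - less)) / n

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneRankTable":
        df = pd.read_csv(path, sep="\t")
        gene_col, z_col = df.columns[:2]
        return cls(dict(zip(df[gene_col].astype(str), df[z_col].astype(float))))

    def __contains__(self, gene: str) -> bool:
        return gene in self.zscores

    def zscore(self, gene: str) -> float:
        return self.zscores[gene]

    def percentile(self, gene: str) -> float:
        """Mid-rank percentile of the gene's Z among all table genes."""
        if gene not in self._percentiles:
            raise KeyError(f"gene {gene!r} not in rank table")
        return self._percentiles[gene]


def gene_percentile(table: GeneRankTable, gene: str) -> float | None:
    """Percentile for one gene; None (and a log entry) when absent."""
    try:
        return table.percentile(gene)
    except KeyError:
        logger.warning("gene %s absent from the rank table; percentile undefined", gene)
        return None


# ---------------------------------------------------------------------------
# Annotated variant records


@dataclass
class AnnotatedVariant:
    """Light-weight view of one annotated VCF record for filtering."""

    chrom: str
    pos: int
    ref: str
    alt: str
    level: int
    genes: set[str] = field(default_factory=set)
    closest_gene: str | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    coding: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def all_genes(self) -> set[str]:
        out = set(self.genes)
        if self.closest_gene:
            out.add(self.closest_gene)
        return out


_CODING_TERMS = (
    "missense", "stop_gained", "stop_lost", "start_lost", "frameshift",
    "inframe", "synonymous", "protein_altering", "splice_donor",
    "splice_acceptor", "coding_sequence",
)


def read_annotated_vcf(path: str | Path) -> list[AnnotatedVariant]:
    """Read RV_*-annotated records (one per ALT allele) from a VCF."""
    import pysam

    def info_get(rec, key, default=None):
        try:
            return rec.info.get(key, default)
        except (KeyError, ValueError):  # key absent from header
            return default

    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            levels = info_get(rec, "RV_LEVEL", ())
            if not isinstance(levels, tuple):
                levels = (levels,)
            genes = set()
            for entry in info_get(rec, "RV_GENES", ()) or ():
                genes.add(entry.split(":")[0])
            ann = info_get(rec, "ANN", ()) or ()
            coding = any(
                any(term in entry.split("|")[1] for term in _CODING_TERMS)
                for entry in ann
                if len(entry.split("|")) > 1
            )
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is not None:
                    gts[s] = tuple(g for g in gt)
            for i, alt in enumerate(rec.alts or ()):
                out.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref or "N",
                        alt=alt or "N",
                        level=int(levels[i]) if i < len(levels) and levels[i] is not None else 0,
                        genes=genes,
                        closest_gene=info_get(rec, "RV_CLOSEST"),
                        genotypes=gts,
                        coding=coding,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# HPO-based prioritization


def hpo_prioritize(
    variants: Sequence[AnnotatedVariant],
    table: GeneRankTable,
    level_min: int = 3,
    percentile_min: float = 0.95,
) -> list[tuple[AnnotatedVariant, str, float]]:
    """Filter by level and gene percentile; rank by best gene Z-score.

    Keeps variants with ``level >= level_min`` that have at least one
    annotated gene at or above ``percentile_min``; each kept variant is
    paired with its best-ranked qualifying gene. Sorted by Z descending,
    ties by genomic order. Genes absent from the table are skipped (never
    silently assigned a percentile).
    """
    kept = []
    for v in variants:
        if v.level < level_min:
            continue
        qualifying = [
            (table.zscore(g), g)
            for g in sorted(v.all_genes)
            if g in table and table.percentile(g) >= percentile_min
        ]
        if not qualifying:
            continue
        z, gene = max(qualifying)
        kept.append((v, gene, z))
    kept.sort(key=lambda t: (-t[2], t[0].chrom, t[0].pos, t[0].ref, t[0].alt))
    return kept


# ---------------------------------------------------------------------------
# Pedigree


@dataclass(frozen=True)
class Sample:
    sample_id: str
    father: str | None
    mother: str | None
    sex: str
    affected: bool


class Pedigree:
    """6-column PED pedigree (family, sample, father, mother, sex, status)."""

    def __init__(self, samples: Sequence[Sample]):
        self.samples = {s.sample_id: s for s in samples}

    @classmethod
    def from_ped(cls, path: str | Path) -> "Pedigree":
        samples = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                _fam, sid, father, mother, sex, status = line.split()[:6]
                samples.append(
                    Sample(
                        sample_id=sid,
                        father=None if father == "0" else father,
                        mother=None if mother == "0" else mother,
                        sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                        affected=status == "2",
                    )
                )
        return cls(samples)

    def trios(self) -> list[tuple[str, str, str]]:
        """(proband, father, mother) triples with both parents present."""
        out = []
        for s in self.samples.values():
            if s.father in self.samples and s.mother in self.samples:
                out.append((s.sample_id, s.father, s.mother))
        return out


# ---------------------------------------------------------------------------
# Segregation


def _gt_class(gt: Genotype | None) -> str | None:
    if gt is None or any(a is None for a in gt):
        return None
    if len(gt) != 2:
        return "non-diploid"
    alts = sum(1 for a in gt if a > 0)
    return ("hom_ref", "het", "hom_alt")[alts]


def segregation_filter(
    variant: AnnotatedVariant,
    trio: tuple[str, str, str],
    model: str = "recessive",
) -> bool:
    """Trio segregation check for one variant.

    recessive: proband hom-alt, both parents het.
    dominant: proband het or hom-alt, both (unaffected) parents hom-ref.
    Missing genotypes fail safe (variant not passed); non-diploid
    genotypes are skipped with a warning.
    """
    if model not in ("recessive", "dominant"):
        raise ValueError(f"unknown inheritance model {model!r}")
    proband, father, mother = trio
    classes = {s: _gt_class(variant.genotypes.get(s)) for s in trio}
    if "non-diploid" in classes.values():
        logger.warning("non-diploid genotype at %s:%d; record skipped", variant.chrom, variant.pos)
        return False
    if None in classes.values():
        return False
    if model == "recessive":
        return (
            classes[proband] == "hom_alt"
            and classes[father] == "het"
            and classes[mother] == "het"
        )
    return classes[proband] in ("het", "hom_alt") and (
        classes[father] == "hom_ref" and classes[mother] == "hom_ref"
    )


# ---------------------------------------------------------------------------
# Compound heterozygotes


@dataclass
class CompHetPair:
    gene: str
    v1: AnnotatedVariant
    v2: AnnotatedVariant
    phase: str  # "trans" or "ambiguous"
    composition: str  # coding+coding | coding+regulatory | regulatory+regulatory


def _parental_origin(v: AnnotatedVariant, trio: tuple[str, str, str]) -> str | None:
    """paternal / maternal / ambiguous for a proband-het variant; None if
    the variant cannot be an inherited het in this trio."""
    proband, father, mother = trio
    if _gt_class(v.genotypes.get(proband)) != "het":
        return None
    f = _gt_class(v.genotypes.get(father))
    m = _gt_class(v.genotypes.get(mother))
    if f is None or m is None:
        return None
    f_has = f in ("het", "hom_alt")
    m_has = m in ("het", "hom_alt")
    if f_has and not m_has:
        return "paternal"
    if m_has and not f_has:
        return "maternal"
    if f_has and m_has:
        return "ambiguous"
    return None  # de novo: not an inherited compound-het partner


def compound_het_pairs(
    variants: Sequence[AnnotatedVariant],
    trio: tuple[str, str, str],
    coding_predicate=None,
) -> list[CompHetPair]:
    """Candidate compound-heterozygote pairs within each gene.

    A pair requires the proband to be het for both variants, with trans
    inheritance inferred from parental genotypes (one allele from each
    parent). When either variant's origin is ambiguous (both parents
    carry it), the pair is kept but flagged "ambiguous". Cis pairs (same
    parental origin) are excluded. Pairs never span genes; each pair is
    reported once with (v1, v2) in genomic order. ``coding_predicate``
    overrides the per-variant coding label when given.
    """
    is_coding = coding_predicate if coding_predicate is not None else (lambda v: v.coding)
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        for gene in sorted(v.all_genes):
            by_gene.setdefault(gene, []).append(v)

    pairs = []
    for gene, vs in sorted(by_gene.items()):
        vs = sorted(vs, key=lambda v: v.key)
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                v1, v2 = vs[i], vs[j]
                if v1.key == v2.key:
                    continue
                o1 = _parental_origin(v1, trio)
                o2 = _parental_origin(v2, trio)
                if o1 is None or o2 is None:
                    continue
                if "ambiguous" in (o1, o2):
                    phase = "ambiguous"
                elif o1 != o2:
                    phase = "trans"
                else:
                    continue  # cis
                c1, c2 = is_coding(v1), is_coding(v2)
                composition = {
                    (True, True): "coding+coding",
                    (True, False): "coding+regulatory",
                    (False, True): "coding+regulatory",
                    (False, False): "regulatory+regulatory",
                }[(c1, c2)]
                pairs.append(CompHetPair(gene, v1, v2, phase, composition))
    return pairs


def write_candidates_tsv(
    candidates: "Iterable[tuple[AnnotatedVariant, str, float]]", path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlevel\tgene\tzscore\n")
        for v, gene, z in candidates:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.level}\t{gene}\t{z:g}\n")
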