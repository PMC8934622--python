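"""VCF annotation with regulatory evidence and 4-level prioritization.

Each variant allele is intersected with the regulatory-region store, with
functional-element BED classes (TFBS, DNase peaks, ultra-conserved
non-coding elements) and with per-position impact-score tracks, then
assigned an evidence level:

  level 1: rare (population AF below ``af_max``) and inside >= 1 region
  level 2: level 1 + overlapping >= 1 functional-element class
  level 3: level 2 + >= 1 score at or above its FDR50 threshold
  level 4: level 3 + max region constraint >= ``constraint_min``

Structural variants get region/gene annotation but no level. Annotation
is written into RV_* INFO fields declared in the header, is idempotent
(existing RV_* fields are replaced), and preserves record counts and
genotype columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from regvaran.region_eval import PositionTrack, load_feature_bed
from regvaran.regiondb import RegionStore, RegulatoryRegion, build_interval_index

logger = logging.getLogger(__name__)

FE_CLASSES = ("TFBS", "DNase", "UCNE")

INFO_FIELDS = {
    "RV_ID": (".", "String", "Overlapping regulatory region ids"),
    "RV_TYPE": (".", "String", "Types of the overlapping regulatory regions"),
    "RV_CONSTRAINT": ("1", "Float", "Maximum constraint value of overlapping regions"),
    "RV_GENES": (".", "String", "Controlled genes as gene:evidence1|evidence2"),
    "RV_CLOSEST": ("1", "String", "Closest gene of the overlapping regions"),
    "RV_DIST": ("1", "Integer", "Signed distance to the closest gene (0 if overlapping)"),
    "RV_FE": (".", "String", "Functional element classes overlapped (TFBS/DNase/UCNE)"),
    "RV_SCORES": (".", "String", "Impact score values at the variant as name:value"),
    "RV_LEVEL": ("A", "Integer", "Regulatory evidence level (0-4) per ALT allele"),
    "RV_VOI": ("0", "Flag", "Variant linked to a gene of interest"),
    "RV_AFMISS": ("0", "Flag", "Population AF missing; treated as rare"),
}


@dataclass
class LevelConfig:
    """Thresholds for the 4-level classification."""

    af_max: float = 0.01  # exclusive gate: AF < af_max
    fe_classes: tuple[str, ...] = FE_CLASSES
    score_thresholds: dict[str, float] = field(default_factory=dict)  # FDR50 cutoffs
    constraint_min: float = 0.7  # inclusive gate
    gado_percentile: float = 0.90
    af_field: str = "AF"
    missing_af_is_rare: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.af_max <= 1.0):
            raise ValueError("af_max must be in (0, 1]")
        if not (0.0 <= self.constraint_min <= 1.0):
            raise ValueError("constraint_min must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LevelConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class VariantAnnotation:
    """Regulatory evidence bundle for one variant allele."""

    chrom: str
    pos: int  # 1-based VCF position
    ref: str
    alt: str
    af: float | None
    region_ids: list[str] = field(default_factory=list)
    region_types: list[str] = field(default_factory=list)
    max_constraint: float | None = None
    genes: dict[str, set[str]] = field(default_factory=dict)  # gene -> evidence classes
    closest_gene: str | None = None
    closest_dist: int | None = None
    fe_hits: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)
    level: int = 0
    voi: bool = False
    af_missing: bool = False

    @property
    def all_genes(self) -> set[str]:
        out = set(self.genes)
        if self.closest_gene:
            out.add(self.closest_gene)
        return out


class FunctionalElements:
    """Named BED classes of functional elements, merged per chromosome."""

    def __init__(self, beds: Mapping[str, object]):
        self.features = {name: load_feature_bed(bed) for name, bed in beds.items()}

    def hit_classes(self, chrom: str, start: int, end: int) -> list[str]:
        hits = []
        for name, feat in self.features.items():
            for s, e in feat.get(chrom, []):
                if s < end and e > start:
                    hits.append(name)
                    break
        return hits


class RegionIndex:
    """In-memory interval index over a region store, with gene links."""

    def __init__(self, store: RegionStore):
        regions = store.all_regions()
        self.trees: dict[str, IntervalTree] = build_interval_index(regions)
        self.gene_links: dict[str, dict[str, set[str]]] = {}
        for r in regions:
            links: dict[str, set[str]] = {}
            for gl in store.gene_links_for(r.region_id):
                links.setdefault(gl.gene_id, set()).add(gl.evidence)
            self.gene_links[r.region_id] = links

    def overlapping(self, chrom: str, start: int, end: int) -> list[RegulatoryRegion]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)), key=lambda r: r.region_id)


def affected_span(pos: int, ref: str) -> tuple[int, int]:
    """Half-open internal span of reference bases affected by an allele."""
    return pos - 1, pos - 1 + max(len(ref), 1)


def score_at_variant(track: PositionTrack, chrom: str, pos: int, ref: str, alt: str) -> float | None:
    """Score value for an allele: SNVs read their position, deletions/MNVs
    take the maximum over affected positions, insertions the maximum of the
    two flanking positions."""
    if len(alt) > len(ref) and len(ref) == 1:  # insertion
        start, end = pos - 1, pos + 1
    else:
        start, end = affected_span(pos, ref)
    vals = track.region_values(chrom, start, end)
    return float(vals.max()) if len(vals) else None


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    af: float | None,
    index: RegionIndex,
    fe: FunctionalElements | None,
    tracks: Mapping[str, PositionTrack],
    config: LevelConfig,
    genes_of_interest: "set[str] | None" = None,
) -> VariantAnnotation:
    """Annotate one allele with regulatory evidence and classify its level."""
    start, end = affected_span(pos, ref)
    regions = index.overlapping(chrom, start, end)

    genes: dict[str, set[str]] = {}
    closest = None
    for r in regions:
        for gene, evs in index.gene_links.get(r.region_id, {}).items():
            genes.setdefault(gene, set()).update(evs)
        if r.closest_gene is not None and r.closest_gene_dist is not None:
            if closest is None or abs(r.closest_gene_dist) < abs(closest[1]):
                closest = (r.closest_gene, r.closest_gene_dist)

    constraints = [r.constraint for r in regions if r.constraint is not None]
    scores = {}
    for name, track in tracks.items():
        v = score_at_variant(track, chrom, pos, ref, alt)
        if v is not None:
            scores[name] = v

    ann = VariantAnnotation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        af=af,
        region_ids=[r.region_id for r in regions],
        region_types=sorted({r.region_type for r in regions}),
        max_constraint=max(constraints) if constraints else None,
        genes=genes,
        closest_gene=closest[0] if closest else None,
        closest_dist=closest[1] if closest else None,
        fe_hits=fe.hit_classes(chrom, start, end) if fe is not None else [],
        scores=scores,
        af_missing=af is None,
    )
    ann.level = classify_level(ann, config)
    if genes_of_interest:
        ann.voi = tag_genes_of_interest(ann, genes_of_interest)
    return ann


def classify_level(ann: VariantAnnotation, config: LevelConfig) -> int:
    """Highest satisfied evidence level (0-4); levels are nested by design."""
    if ann.af is None:
        rare = config.missing_af_is_rare
    else:
        rare = ann.af < config.af_max
    if not rare or not ann.region_ids:
        return 0
    level = 1
    if not any(c in ann.fe_hits for c in config.fe_classes):
        return level
    level = 2
    above = any(
        name in config.score_thresholds and value >= config.score_thresholds[name]
        for name, value in ann.scores.items()
    )
    if not above:
        return level
    level = 3
    if ann.max_constraint is not None and ann.max_constraint >= config.constraint_min:
        level = 4
    return level


def tag_genes_of_interest(ann: VariantAnnotation, gene_list: set[str]) -> bool:
    """Flag when any controlled or closest gene is in the list of interest."""
    return bool(ann.all_genes & gene_list)


# ---------------------------------------------------------------------------
# Structural variants


def sv_spans(
    chrom: str, pos: int, ref: str, alts: Sequence[str], info: Mapping
) -> list[tuple[str, int, int]] | None:
    """Affected spans for a structural variant; None if undeterminable.

    BND alleles are annotated at each breakend position (one span per
    record; the mate is annotated from its own record). Other SVs span
    POS..END (or POS..POS+|SVLEN|).
    """
    svtype = _info_get(info, "SVTYPE")
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    is_bnd = svtype == "BND" or any("[" in a or "]" in a for a in alts if a)
    if is_bnd:
        return [(chrom, pos - 1, pos)]
    end = _info_get(info, "END")
    svlen = _info_get(info, "SVLEN")
    if isinstance(svlen, tuple):
        svlen = svlen[0]
    if end is not None:
        return [(chrom, pos - 1, int(end))]
    if svlen is not None:
        return [(chrom, pos - 1, pos - 1 + abs(int(svlen)))]
    return None


def annotate_sv(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    info: Mapping,
    index: RegionIndex,
) -> "tuple[list[str], set[str]] | None":
    """Region ids and controlled-gene union for a structural variant.

    No level is assigned: a large variant typically overlaps many regions.
    Returns None when the span is undeterminable (missing END and SVLEN on
    a non-BND record).
    """
    spans = sv_spans(chrom, pos, ref, alts, info)
    if spans is None:
        return None
    region_ids: list[str] = []
    genes: set[str] = set()
    for c, s, e in spans:
        for r in index.overlapping(c, s, e):
            if r.region_id not in region_ids:
                region_ids.append(r.region_id)
            genes.update(index.gene_links.get(r.region_id, {}))
    return region_ids, genes


# ---------------------------------------------------------------------------
# Consequence update


def update_consequence(
    existing: "Sequence[str] | None",
    regulatory_genes: Iterable[str],
    style: str = "ANN",
    allele: str = ".",
) -> tuple[list[str], int]:
    """Append regulatory_region_variant entries for genes not yet annotated.

    ``existing`` is the list of ANN (snpEff: Allele|Annotation|Impact|
    Gene_Name|Gene_ID|...) or BCSQ (bcftools: consequence|gene|...) entries;
    existing entries are never modified. Returns (updated entries, number
    appended). Unparseable entries are kept untouched.
    """
    entries = list(existing) if existing else []
    gene_idx = 3 if style == "ANN" else 1
    present: set[str] = set()
    for entry in entries:
        parts = entry.split("|")
        if len(parts) > gene_idx:
            present.add(parts[gene_idx])
        else:
            logger.warning("unparseable consequence entry kept unchanged: %r", entry)
    added = 0
    for gene in sorted(set(regulatory_genes) - present):
        if style == "ANN":
            entries.append(f"{allele}|regulatory_region_variant|MODIFIER|{gene}|{gene}")
        else:
            entries.append(f"regulatory_region_variant|{gene}")
        added += 1
    return entries, added


# ---------------------------------------------------------------------------
# VCF driver


def _info_get(info: Mapping, key: str, default=None):
    # pysam raises on .get() for keys absent from the header
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _allele_af(rec, config: LevelConfig, allele_index: int) -> float | None:
    raw = _info_get(rec.info, config.af_field)
    if raw is None:
        return None
    if isinstance(raw, tuple):
        if allele_index < len(raw):
            raw = raw[allele_index]
        else:
            raw = raw[0]
    try:
        return float(raw)
    except (TypeError, ValueError):
        return None


def annotate_vcf(
    in_vcf: str | Path,
    out_vcf: str | Path,
    store: RegionStore,
    fe_beds: Mapping[str, object] | None = None,
    tracks: Mapping[str, PositionTrack] | None = None,
    config: LevelConfig | None = None,
    genes_of_interest: "set[str] | None" = None,
    update_ann: bool = False,
) -> dict:
    """Annotate a VCF with RV_* INFO fields; returns per-level counts.

    Record order, count and genotype columns are preserved; the header
    gains only the declared RV_* INFO lines. Re-annotating an annotated
    file replaces the RV_* fields rather than duplicating them. SV records
    (SVTYPE present or symbolic/breakend ALT) receive region and gene
    annotation without a level.
    """
    import pysam

    config = config or LevelConfig()
    tracks = tracks or {}
    fe = FunctionalElements(fe_beds) if fe_beds else FunctionalElements({})
    index = RegionIndex(store)

    stats = {"records": 0, "skipped": 0, "sv": 0, "levels": {k: 0 for k in range(5)}}

    with pysam.VariantFile(str(in_vcf)) as vin:
        header = vin.header.copy()
        for name, (number, vtype, desc) in INFO_FIELDS.items():
            if name not in header.info:
                header.info.add(name, number, vtype, desc)
        with pysam.VariantFile(str(out_vcf), "w", header=header) as vout:
            for rec in vin:
                stats["records"] += 1
                out = rec.copy()
                out.translate(header)
                for key in list(out.info):
                    if key.startswith("RV_"):
                        del out.info[key]

                alts = rec.alts or ()
                svtype = _info_get(rec.info, "SVTYPE")
                is_sv = svtype is not None or any(
                    a and (a.startswith("<") or "[" in a or "]" in a) for a in alts
                )
                if is_sv:
                    result = annotate_sv(rec.chrom, rec.pos, rec.ref or "N", alts, rec.info, index)
                    if result is None:
                        stats["skipped"] += 1
                        vout.write(out)
                        continue
                    region_ids, genes = result
                    stats["sv"] += 1
                    if region_ids:
                        out.info["RV_ID"] = tuple(region_ids)
                        if genes:
                            out.info["RV_GENES"] = tuple(sorted(genes))
                    vout.write(out)
                    continue

                anns = []
                for i, alt in enumerate(alts):
                    try:
                        anns.append(
                            annotate_variant(
                                rec.chrom,
                                rec.pos,
                                rec.ref or "N",
                                alt or "N",
                                _allele_af(rec, config, i),
                                index,
                                fe,
                                tracks,
                                config,
                                genes_of_interest,
                            )
                        )
                    except Exception:
                        stats["skipped"] += 1
                if anns:
                    _write_info(out, anns)
                    if update_ann and "ANN" in header.info:
                        reg_genes = set().union(*(a.all_genes for a in anns))
                        if reg_genes:
                            existing = out.info.get("ANN")
                            updated, _ = update_consequence(
                                existing, reg_genes, style="ANN", allele=alts[0] or "."
                            )
                            out.info["ANN"] = tuple(updated)
                    best = max(a.level for a in anns)
                    stats["levels"][best] += 1
                vout.write(out)
    return stats


def _write_info(out, anns: "list[VariantAnnotation]") -> None:
    region_ids = sorted({rid for a in anns for rid in a.region_ids})
    if region_ids:
        out.info["RV_ID"] = tuple(region_ids)
        out.info["RV_TYPE"] = tuple(sorted({t for a in anns for t in a.region_types}))
    constraints = [a.max_constraint for a in anns if a.max_constraint is not None]
    if constraints:
        out.info["RV_CONSTRAINT"] = max(constraints)
    genes: dict[str, set[str]] = {}
    for a in anns:
        for g, evs in a.genes.items():
            genes.setdefault(g, set()).update(evs)
    if genes:
        out.info["RV_GENES"] = tuple(f"{g}:{'|'.join(sorted(evs))}" for g, evs in sorted(genes.items()))
    closest = [(a.closest_gene, a.closest_dist) for a in anns if a.closest_gene]
    if closest:
        gene, dist = min(closest, key=lambda cd: abs(cd[1]))
        out.info["RV_CLOSEST"] = gene
        out.info["RV_DIST"] = dist
    fe_hits = sorted({h for a in anns for h in a.fe_hits})
    if fe_hits:
        out.info["RV_FE"] = tuple(fe_hits)
    scores: dict[str, float] = {}
    for a in anns:
        for name, v in a.scores.items():
            scores[name] = max(scores.get(name, float("-inf")), v)
    if scores:
        out.info["RV_SCORES"] = tuple(f"{n}:{v:g}" for n, v in sorted(scores.items()))
    out.info["RV_LEVEL"] = tuple(a.level for a in anns)
    if any(a.voi for a in anns):
        out.info["RV_VOI"] = True
    if all(a.af_missing for a in anns):
        out.info["RV_AFMISS"] = True
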