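"""Regulatory-region database: normalization, collapsing, gene linking, storage.

Heterogeneous source tables (each with its own column names and coordinate
convention) are normalized into :class:`RegulatoryRegion` records with a
five-class type vocabulary (bivalent, enhancer, insulator, promoter,
silencer), collapsed to remove redundancy between sources, linked to their
closest gene and closest transcription start site, and serialized into a
single-file SQLite store that supports interval, gene and id queries, plus
an extended-BED export that round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

REGION_TYPES = frozenset({"bivalent", "enhancer", "insulator", "promoter", "silencer"})
GENE_EVIDENCE = frozenset({"direct", "closest_gene", "closest_tss", "eqtl"})
PHENOTYPE_PROVENANCE = frozenset({"gwas", "hpo", "curated"})


@dataclass
class RegulatoryRegion:
    """One normalized regulatory region (0-based half-open coordinates)."""

    region_id: str
    chrom: str
    start: int
    end: int
    region_type: str
    sources: set[str] = field(default_factory=set)
    methods: set[str] = field(default_factory=set)
    tissues: set[str] = field(default_factory=set)
    closest_gene: str | None = None
    closest_gene_dist: int | None = None  # signed: <0 gene upstream of region start
    closest_tss_gene: str | None = None
    closest_tss_dist: int | None = None
    constraint: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.region_id}: end ({self.end}) <= start ({self.start})")
        if self.region_type not in REGION_TYPES:
            raise ValueError(f"{self.region_id}: unknown region type {self.region_type!r}")
        if self.constraint is not None and not (0.0 <= self.constraint <= 1.0):
            raise ValueError(f"{self.region_id}: constraint {self.constraint} outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GeneLink:
    region_id: str
    gene_id: str
    evidence: str  # direct | closest_gene | closest_tss | eqtl
    tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.evidence not in GENE_EVIDENCE:
            raise ValueError(f"unknown gene-link evidence {self.evidence!r}")


@dataclass(frozen=True)
class PhenotypeLink:
    region_id: str
    phenotype: str  # free text or HPO id
    provenance: str  # gwas | hpo | curated

    def __post_init__(self) -> None:
        if self.provenance not in PHENOTYPE_PROVENANCE:
            raise ValueError(f"unknown phenotype provenance {self.provenance!r}")


@dataclass(frozen=True)
class GeneModel:
    """Gene span with a strand-dependent transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        # half-open convention: for '-' genes the TSS base is end-1
        return self.start if self.strand == "+" else self.end - 1


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, start, end, strand[, biotype])."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                biotype=str(getattr(row, "biotype", "protein_coding")),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class SourceMeta:
    """Describes how one raw region table maps onto the internal schema.

    ``columns`` maps internal field names (chrom, start, end, type, and
    optionally method, tissue) to the raw table's column names.
    ``coords`` declares the dialect: "0-based" (half-open, BED-like) or
    "1-based" (closed, GFF-like); 1-based closed records are converted by
    decrementing the start.
    ``type_map`` optionally maps raw type labels to the five-class
    vocabulary; raw labels are lower-cased before lookup.
    """

    name: str
    columns: dict[str, str]
    coords: str = "0-based"
    type_map: dict[str, str] | None = None


@dataclass
class RejectionReport:
    source: str
    n_input: int = 0
    n_accepted: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (record repr, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def normalize_source(
    raw_table: pd.DataFrame | str | Path,
    source_meta: SourceMeta,
    genome: "object | None" = None,
    id_prefix: str | None = None,
) -> tuple[list[RegulatoryRegion], RejectionReport]:
    """Normalize one raw region table into RegulatoryRegion records.

    Records with unknown chromosome (when a genome is given), end <= start
    after conversion, or an unmappable type are dropped and counted in the
    returned :class:`RejectionReport`. A missing mandatory column rejects
    the whole source with ``KeyError``.
    """
    if not isinstance(raw_table, pd.DataFrame):
        raw_table = pd.read_csv(raw_table, sep="\t")
    for fieldname in ("chrom", "start", "end", "type"):
        if fieldname not in source_meta.columns:
            raise KeyError(f"source {source_meta.name!r}: no column mapping for {fieldname!r}")
        if source_meta.columns[fieldname] not in raw_table.columns:
            raise KeyError(
                f"source {source_meta.name!r}: mandatory column "
                f"{source_meta.columns[fieldname]!r} absent from table"
            )
    if source_meta.coords not in ("0-based", "1-based"):
        raise ValueError(f"unknown coordinate convention {source_meta.coords!r}")

    cols = source_meta.columns
    prefix = id_prefix if id_prefix is not None else source_meta.name
    report = RejectionReport(source=source_meta.name, n_input=len(raw_table))
    regions: list[RegulatoryRegion] = []
    for i, row in enumerate(raw_table.itertuples(index=False)):
        rec = row._asdict()
        chrom = str(rec[cols["chrom"]])
        start = int(rec[cols["start"]])
        end = int(rec[cols["end"]])
        if source_meta.coords == "1-based":
            start -= 1  # 1-based closed -> 0-based half-open
        raw_type = str(rec[cols["type"]])
        key = raw_type.lower()
        if source_meta.type_map is not None and key in source_meta.type_map:
            rtype = source_meta.type_map[key]
        else:
            rtype = key
        if genome is not None and chrom not in genome:
            report.rejected.append((f"{chrom}:{start}-{end}", "unknown chromosome"))
            continue
        if end <= start:
            report.rejected.append((f"{chrom}:{start}-{end}", "end <= start"))
            continue
        if rtype not in REGION_TYPES:
            report.rejected.append((f"{chrom}:{start}-{end}", f"unmappable type {raw_type!r}"))
            continue
        tissues = set()
        if "tissue" in cols and cols["tissue"] in rec and pd.notna(rec[cols["tissue"]]):
            tissues = {t for t in str(rec[cols["tissue"]]).split(",") if t}
        methods = set()
        if "method" in cols and cols["method"] in rec and pd.notna(rec[cols["method"]]):
            methods = {m for m in str(rec[cols["method"]]).split(",") if m}
        regions.append(
            RegulatoryRegion(
                region_id=f"{prefix}_{i:06d}",
                chrom=chrom,
                start=start,
                end=end,
                region_type=rtype,
                sources={source_meta.name},
                methods=methods,
                tissues=tissues,
            )
        )
    report.n_accepted = len(regions)
    return regions, report


# ---------------------------------------------------------------------------
# Collapsing


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len_a, overlap/len_b) for two half-open intervals."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _collapse_once(
    regions: Sequence[RegulatoryRegion], threshold: float
) -> tuple[list[RegulatoryRegion], bool]:
    # union-find over regions grouped by (chrom, type); candidates found by sweep
    parent = list(range(len(regions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    groups: dict[tuple[str, str], list[int]] = {}
    for idx, r in enumerate(regions):
        groups.setdefault((r.chrom, r.region_type), []).append(idx)

    merged_any = False
    for idxs in groups.values():
        idxs.sort(key=lambda i: (regions[i].start, regions[i].end))
        active: list[int] = []
        for i in idxs:
            ri = regions[i]
            active = [j for j in active if regions[j].end > ri.start]
            for j in active:
                if reciprocal_overlap(
                    (ri.start, ri.end), (regions[j].start, regions[j].end)
                ) >= threshold:
                    union(i, j)
                    merged_any = True
            active.append(i)

    components: dict[int, list[int]] = {}
    for i in range(len(regions)):
        components.setdefault(find(i), []).append(i)

    out: list[RegulatoryRegion] = []
    for members in components.values():
        members.sort()
        first = regions[members[0]]
        if len(members) == 1:
            out.append(first)
            continue
        group = [regions[i] for i in members]
        out.append(
            RegulatoryRegion(
                region_id=min(r.region_id for r in group),
                chrom=first.chrom,
                start=min(r.start for r in group),
                end=max(r.end for r in group),
                region_type=first.region_type,
                sources=set().union(*(r.sources for r in group)),
                methods=set().union(*(r.methods for r in group)),
                tissues=set().union(*(r.tissues for r in group)),
            )
        )
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.region_type))
    return out, merged_any


def collapse_regions(
    regions: Sequence[RegulatoryRegion], reciprocal_overlap_threshold: float = 0.8
) -> list[RegulatoryRegion]:
    """Collapse same-type regions with reciprocal overlap >= threshold.

    Merging is transitive (connected components of the pairwise relation)
    and applied to the merged union spans until a fixed point, so the
    operation is idempotent. Provenance sets (sources, methods, tissues)
    are unioned; regions of different types are never merged, even at
    identical coordinates. The merged region keeps the lexicographically
    smallest member id.
    """
    if not (0.0 < reciprocal_overlap_threshold <= 1.0):
        raise ValueError("reciprocal overlap threshold must be in (0, 1]")
    current = list(regions)
    while True:
        current, merged = _collapse_once(current, reciprocal_overlap_threshold)
        if not merged:
            return current


# ---------------------------------------------------------------------------
# Closest gene / TSS


def _gap_and_sign(region: RegulatoryRegion, gene: GeneModel) -> tuple[int, int]:
    """(gap distance, signed distance). 0 if overlapping; negative sign when
    the gene lies before the region start."""
    if gene.end <= region.start:
        gap = region.start - gene.end
        return gap, -gap
    if gene.start >= region.end:
        gap = gene.start - region.end
        return gap, gap
    return 0, 0


def assign_closest(
    regions: Iterable[RegulatoryRegion], genes: Sequence[GeneModel]
) -> list[RegulatoryRegion]:
    """Fill closest_gene (gap distance, signed) and closest_tss (midpoint
    distance) on each region; ties broken by smaller gene id."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out = []
    for region in regions:
        cands = by_chrom.get(region.chrom)
        if not cands:
            logger.warning("no gene on chromosome %s; closest fields left undefined", region.chrom)
            out.append(region)
            continue
        best_gene = min(cands, key=lambda g: (abs(_gap_and_sign(region, g)[0]), g.gene_id))
        _, signed = _gap_and_sign(region, best_gene)
        best_tss = min(cands, key=lambda g: (abs(region.midpoint - g.tss), g.gene_id))
        out.append(
            replace(
                region,
                closest_gene=best_gene.gene_id,
                closest_gene_dist=signed,
                closest_tss_gene=best_tss.gene_id,
                closest_tss_dist=int(abs(region.midpoint - best_tss.tss)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# SQLite store

_SCHEMA = """
CREATE TABLE regions (
    region_id TEXT PRIMARY KEY,
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    region_type TEXT NOT NULL,
    methods TEXT NOT NULL,
    tissues TEXT NOT NULL,
    closest_gene TEXT,
    closest_gene_dist INTEGER,
    closest_tss_gene TEXT,
    closest_tss_dist INTEGER,
    constraint_value REAL
);
CREATE TABLE sources (
    region_id TEXT NOT NULL REFERENCES regions(region_id),
    source TEXT NOT NULL,
    PRIMARY KEY (region_id, source)
);
CREATE TABLE gene_links (
    region_id TEXT NOT NULL REFERENCES regions(region_id),
    gene_id TEXT NOT NULL,
    evidence TEXT NOT NULL,
    tissues TEXT NOT NULL,
    PRIMARY KEY (region_id, gene_id, evidence)
);
CREATE TABLE phenotype_links (
    region_id TEXT NOT NULL REFERENCES regions(region_id),
    phenotype TEXT NOT NULL,
    provenance TEXT NOT NULL
);
CREATE INDEX idx_regions_interval ON regions(chrom, start, end);
CREATE INDEX idx_gene_links_gene ON gene_links(gene_id);
"""


class RegionStore:
    """Single-file SQLite store of regions, gene links and phenotype links.

    Supports interval queries, gene queries, region-id queries and detail
    retrieval; `build` followed by `dump` reproduces the input sets exactly.
    """

    def __init__(self, conn: sqlite3.Connection):
        self.conn = conn

    # -- construction -------------------------------------------------------

    @classmethod
    def build(
        cls,
        regions: Sequence[RegulatoryRegion],
        gene_links: Sequence[GeneLink] = (),
        phenotype_links: Sequence[PhenotypeLink] = (),
        path: str | Path = ":memory:",
    ) -> "RegionStore":
        ids = {r.region_id for r in regions}
        if len(ids) != len(regions):
            seen: set[str] = set()
            dupes = sorted({r.region_id for r in regions if r.region_id in seen or seen.add(r.region_id)})
            raise ValueError(f"duplicate region ids: {dupes}")
        dangling = sorted(
            {l.region_id for l in gene_links if l.region_id not in ids}
            | {l.region_id for l in phenotype_links if l.region_id not in ids}
        )
        if dangling:
            raise ValueError(f"links reference unknown region ids: {dangling}")

        if path != ":memory:":
            Path(path).unlink(missing_ok=True)
        conn = sqlite3.connect(str(path))
        conn.executescript(_SCHEMA)
        conn.executemany(
            "INSERT INTO regions VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            [
                (
                    r.region_id,
                    r.chrom,
                    r.start,
                    r.end,
                    r.region_type,
                    json.dumps(sorted(r.methods)),
                    json.dumps(sorted(r.tissues)),
                    r.closest_gene,
                    r.closest_gene_dist,
                    r.closest_tss_gene,
                    r.closest_tss_dist,
                    r.constraint,
                )
                for r in regions
            ],
        )
        conn.executemany(
            "INSERT INTO sources VALUES (?,?)",
            [(r.region_id, s) for r in regions for s in sorted(r.sources)],
        )
        conn.executemany(
            "INSERT INTO gene_links VALUES (?,?,?,?)",
            [
                (l.region_id, l.gene_id, l.evidence, json.dumps(sorted(l.tissues)))
                for l in gene_links
            ],
        )
        conn.executemany(
            "INSERT INTO phenotype_links VALUES (?,?,?)",
            [(l.region_id, l.phenotype, l.provenance) for l in phenotype_links],
        )
        conn.commit()
        return cls(conn)

    @classmethod
    def open(cls, path: str | Path) -> "RegionStore":
        return cls(sqlite3.connect(str(path)))

    def close(self) -> None:
        self.conn.close()

    # -- queries ------------------------------------------------------------

    def _rows_to_regions(self, rows: Iterable[tuple]) -> list[RegulatoryRegion]:
        out = []
        for row in rows:
            (rid, chrom, start, end, rtype, methods, tissues,
             cg, cgd, ctg, ctd, constraint) = row
            srcs = {
                s for (s,) in self.conn.execute(
                    "SELECT source FROM sources WHERE region_id = ?", (rid,)
                )
            }
            out.append(
                RegulatoryRegion(
                    region_id=rid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    region_type=rtype,
                    sources=srcs,
                    methods=set(json.loads(methods)),
                    tissues=set(json.loads(tissues)),
                    closest_gene=cg,
                    closest_gene_dist=cgd,
                    closest_tss_gene=ctg,
                    closest_tss_dist=ctd,
                    constraint=constraint,
                )
            )
        return out

    def query_interval(self, chrom: str, start: int, end: int) -> list[RegulatoryRegion]:
        """Regions overlapping the half-open interval [start, end) on chrom."""
        rows = self.conn.execute(
            "SELECT * FROM regions WHERE chrom = ? AND start < ? AND end > ? "
            "ORDER BY start, end, region_id",
            (chrom, end, start),
        )
        return self._rows_to_regions(rows)

    def query_gene(self, gene_id: str) -> list[RegulatoryRegion]:
        """Regions linked to a gene by any evidence class."""
        rows = self.conn.execute(
            "SELECT DISTINCT r.* FROM regions r JOIN gene_links g USING (region_id) "
            "WHERE g.gene_id = ? ORDER BY r.chrom, r.start",
            (gene_id,),
        )
        return self._rows_to_regions(rows)

    def query_ids(self, region_ids: Iterable[str]) -> tuple[list[RegulatoryRegion], list[str]]:
        """Look up regions by id; returns (found, not_found)."""
        found, missing = [], []
        for rid in region_ids:
            rows = list(self.conn.execute("SELECT * FROM regions WHERE region_id = ?", (rid,)))
            if rows:
                found.extend(self._rows_to_regions(rows))
            else:
                missing.append(rid)
        return found, missing

    def gene_links_for(self, region_id: str) -> list[GeneLink]:
        return [
            GeneLink(region_id, gid, ev, frozenset(json.loads(tis)))
            for gid, ev, tis in self.conn.execute(
                "SELECT gene_id, evidence, tissues FROM gene_links WHERE region_id = ? "
                "ORDER BY gene_id, evidence",
                (region_id,),
            )
        ]

    def phenotype_links_for(self, region_id: str) -> list[PhenotypeLink]:
        return [
            PhenotypeLink(region_id, phe, prov)
            for phe, prov in self.conn.execute(
                "SELECT phenotype, provenance FROM phenotype_links WHERE region_id = ? "
                "ORDER BY phenotype",
                (region_id,),
            )
        ]

    def all_regions(self) -> list[RegulatoryRegion]:
        rows = self.conn.execute("SELECT * FROM regions ORDER BY chrom, start, end, region_id")
        return self._rows_to_regions(rows)

    def dump(self) -> tuple[list[RegulatoryRegion], list[GeneLink], list[PhenotypeLink]]:
        regions = self.all_regions()
        glinks = [gl for r in regions for gl in self.gene_links_for(r.region_id)]
        plinks = [pl for r in regions for pl in self.phenotype_links_for(r.region_id)]
        return regions, glinks, plinks

    def set_constraint(self, values: dict[str, float]) -> None:
        """Write constraint values back into the store."""
        self.conn.executemany(
            "UPDATE regions SET constraint_value = ? WHERE region_id = ?",
            [(v, rid) for rid, v in values.items()],
        )
        self.conn.commit()

    def query_details(
        self,
        interval: tuple[str, int, int] | None = None,
        gene: str | None = None,
        region_ids: Iterable[str] | None = None,
        vcf: str | Path | None = None,
    ) -> dict:
        """Detailed records for the selected regions.

        Exactly one selector should be given; a VCF selector returns the
        union of per-variant interval queries. Unknown region ids go into
        the "not_found" list rather than raising.
        """
        not_found: list[str] = []
        if interval is not None:
            regions = self.query_interval(*interval)
        elif gene is not None:
            regions = self.query_gene(gene)
        elif region_ids is not None:
            regions, not_found = self.query_ids(region_ids)
        elif vcf is not None:
            import pysam

            seen: dict[str, RegulatoryRegion] = {}
            with pysam.VariantFile(str(vcf)) as vf:
                for rec in vf:
                    start = rec.pos - 1  # VCF 1-based -> internal 0-based
                    end = start + max(len(rec.ref or "N"), 1)
                    for r in self.query_interval(rec.chrom, start, end):
                        seen[r.region_id] = r
            regions = sorted(seen.values(), key=lambda r: (r.chrom, r.start, r.region_id))
        else:
            raise ValueError("one selector (interval, gene, region_ids, vcf) is required")

        records = []
        for r in regions:
            genes_by_ev: dict[str, list[str]] = {}
            for gl in self.gene_links_for(r.region_id):
                genes_by_ev.setdefault(gl.evidence, []).append(gl.gene_id)
            records.append(
                {
                    "region_id": r.region_id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "type": r.region_type,
                    "sources": sorted(r.sources),
                    "methods": sorted(r.methods),
                    "tissues": sorted(r.tissues),
                    "genes": genes_by_ev,
                    "phenotypes": [
                        {"phenotype": pl.phenotype, "provenance": pl.provenance}
                        for pl in self.phenotype_links_for(r.region_id)
                    ],
                    "constraint": r.constraint,
                }
            )
        return {"records": records, "not_found": not_found}

    # -- coverage & export --------------------------------------------------

    def genome_coverage(self, genome) -> float:
        """Union of region spans / total genome length."""
        from regvaran.genome import covered_bases

        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in self.all_regions():
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        covered = sum(covered_bases(ivs) for ivs in by_chrom.values())
        return covered / genome.total_length

    def export_bed(self, path: str | Path) -> None:
        export_bed(self.all_regions(), path)


BED_COLUMNS = [
    "chrom", "start", "end", "region_id", "constraint", "strand",
    "region_type", "sources", "genes",
]


def export_bed(regions: Sequence[RegulatoryRegion], path: str | Path) -> None:
    """Write regions as an extended BED6+3 (sorted by chrom, start)."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.region_id))
    with open(path, "w") as fh:
        for r in rows:
            constraint = "." if r.constraint is None else format(r.constraint, "g")
            genes = r.closest_gene if r.closest_gene else "."
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.region_id,
                        constraint,
                        ".",
                        r.region_type,
                        ",".join(sorted(r.sources)) or ".",
                        genes,
                    ]
                )
                + "\n"
            )


def import_bed(path: str | Path) -> list[RegulatoryRegion]:
    """Read back an extended BED produced by :func:`export_bed`."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, rid, constraint, _strand, rtype, sources, genes = (
                line.rstrip("\n").split("\t")
            )
            regions.append(
                RegulatoryRegion(
                    region_id=rid,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    region_type=rtype,
                    sources=set() if sources == "." else set(sources.split(",")),
                    closest_gene=None if genes == "." else genes,
                    constraint=None if constraint == "." else float(constraint),
                )
            )
    return regions


def build_interval_index(regions: Iterable[RegulatoryRegion]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over regions (payload: the region)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees
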