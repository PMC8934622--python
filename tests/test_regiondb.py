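"""Region normalization, collapsing, closest-gene assignment and the store."""

import numpy as np
import pandas as pd
import pytest

from regvaran.genome import GenomeModel, covered_bases
from regvaran.regiondb import (
    GeneLink,
    GeneModel,
    PhenotypeLink,
    RegionStore,
    RegulatoryRegion,
    SourceMeta,
    assign_closest,
    collapse_regions,
    export_bed,
    import_bed,
    normalize_source,
    reciprocal_overlap,
)
from tests.conftest import SIM_META


def region(rid, chrom, start, end, rtype="enhancer", **kw):
    return RegulatoryRegion(rid, chrom, start, end, rtype, **kw)


# ---------------------------------------------------------------------------
# normalize_source


class TestNormalizeSource:
    def test_one_based_inclusive_converted_to_half_open(self):
        table = pd.DataFrame({"c": ["chr1"], "s": [101], "e": [200], "t": ["Enhancer"]})
        meta = SourceMeta("src", {"chrom": "c", "start": "s", "end": "e", "type": "t"}, "1-based")
        regions, report = normalize_source(table, meta)
        assert (regions[0].chrom, regions[0].start, regions[0].end) == ("chr1", 100, 200)
        assert regions[0].region_type == "enhancer"
        assert report.n_rejected == 0

    def test_degenerate_interval_dropped_and_counted(self):
        table = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 300], "end": [100, 400],
             "type": ["enhancer", "promoter"]}
        )
        meta = SourceMeta("src", {"chrom": "chrom", "start": "start", "end": "end", "type": "type"})
        regions, report = normalize_source(table, meta)
        assert len(regions) == 1
        assert report.n_rejected == 1
        assert report.rejected[0][1] == "end <= start"

    def test_three_sources_of_two_regions_each_keep_provenance(self):
        all_regions = []
        for name in ("srcA", "srcB", "srcC"):
            table = pd.DataFrame(
                {"chrom": ["chr1", "chr2"], "start": [0, 50], "end": [10, 90],
                 "type": ["silencer", "insulator"]}
            )
            meta = SourceMeta(name, {"chrom": "chrom", "start": "start", "end": "end", "type": "type"})
            regions, _ = normalize_source(table, meta)
            all_regions.extend(regions)
        assert len(all_regions) == 6
        for r in all_regions:
            assert len(r.sources) == 1

    def test_unmappable_type_rejected_with_reason(self):
        table = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "type": ["weird"]})
        meta = SourceMeta("src", {"chrom": "chrom", "start": "start", "end": "end", "type": "type"})
        regions, report = normalize_source(table, meta)
        assert regions == []
        assert "unmappable type" in report.rejected[0][1]

    def test_type_map_translates_source_vocabulary(self):
        table = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "type": ["E-P"]})
        meta = SourceMeta(
            "src", {"chrom": "chrom", "start": "start", "end": "end", "type": "type"},
            type_map={"e-p": "bivalent"},
        )
        regions, _ = normalize_source(table, meta)
        assert regions[0].region_type == "bivalent"

    def test_missing_mandatory_column_rejects_source(self):
        table = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        meta = SourceMeta("src", {"chrom": "chrom", "start": "start", "end": "end", "type": "type"})
        with pytest.raises(KeyError):
            normalize_source(table, meta)

    def test_unknown_chromosome_dropped_when_genome_given(self):
        genome = GenomeModel({"chr1": 1000})
        table = pd.DataFrame({"chrom": ["chrUn"], "start": [0], "end": [10], "type": ["enhancer"]})
        meta = SourceMeta("src", {"chrom": "chrom", "start": "start", "end": "end", "type": "type"})
        regions, report = normalize_source(table, meta, genome)
        assert regions == [] and report.rejected[0][1] == "unknown chromosome"


# ---------------------------------------------------------------------------
# collapse_regions


class TestCollapseRegions:
    def test_high_overlap_pair_merges_to_union_span(self):
        a = region("a", "chr1", 0, 100, sources={"s1"})
        b = region("b", "chr1", 10, 110, sources={"s2"})
        assert reciprocal_overlap((0, 100), (10, 110)) == pytest.approx(0.9)
        merged = collapse_regions([a, b], 0.8)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 110)
        assert merged[0].sources == {"s1", "s2"}

    def test_identical_coordinates_different_types_never_merge(self):
        a = region("a", "chr1", 0, 100, "enhancer")
        b = region("b", "chr1", 0, 100, "promoter")
        assert len(collapse_regions([a, b], 0.8)) == 2

    def test_disjoint_regions_unchanged(self):
        rs = [region("a", "chr1", 0, 100), region("b", "chr1", 500, 600)]
        out = collapse_regions(rs, 0.8)
        assert {(r.start, r.end) for r in out} == {(0, 100), (500, 600)}

    def test_below_threshold_pair_not_merged(self):
        a = region("a", "chr1", 0, 100)
        b = region("b", "chr1", 50, 150)  # RO = 0.5
        assert len(collapse_regions([a, b], 0.8)) == 2

    def test_transitive_chain_merges_as_one_component(self):
        rs = [region(f"r{i}", "chr1", i * 5, i * 5 + 100) for i in range(3)]
        # adjacent pairs RO = 0.95, ends RO = 0.9: one component either way
        out = collapse_regions(rs, 0.92)
        assert len(out) == 1 and (out[0].start, out[0].end) == (0, 110)

    def test_collapse_is_idempotent_on_random_fixtures(self, regions):
        once = collapse_regions(regions, 0.8)
        twice = collapse_regions(once, 0.8)
        assert [(r.region_id, r.start, r.end) for r in once] == [
            (r.region_id, r.start, r.end) for r in twice
        ]

    def test_collapse_preserves_coverage_and_reduces_count(self, regions):
        out = collapse_regions(regions, 0.5)
        assert len(out) <= len(regions)
        for rtype in {r.region_type for r in regions}:
            before = covered_bases(
                (r.start, r.end) for r in regions if r.region_type == rtype and r.chrom == "chr1"
            )
            after = covered_bases(
                (r.start, r.end) for r in out if r.region_type == rtype and r.chrom == "chr1"
            )
            assert after >= before


# ---------------------------------------------------------------------------
# assign_closest


class TestAssignClosest:
    def test_region_inside_gene_body_has_distance_zero(self):
        g = GeneModel("G1", "chr1", 0, 10_000, "+")
        (r,) = assign_closest([region("r", "chr1", 100, 200)], [g])
        assert r.closest_gene == "G1" and r.closest_gene_dist == 0

    def test_equidistant_tie_broken_lexicographically(self):
        # genes at equal 1 kb gaps on both sides of the region
        r = region("r", "chr1", 4000, 5000)
        ga = GeneModel("A", "chr1", 6000, 7000, "+")
        gb = GeneModel("B", "chr1", 2000, 3000, "+")
        (out,) = assign_closest([r], [ga, gb])
        assert out.closest_gene == "A"

    def test_tss_uses_strand_dependent_end(self):
        g_plus = GeneModel("P", "chr1", 1000, 2000, "+")
        g_minus = GeneModel("M", "chr1", 1000, 2000, "-")
        assert g_plus.tss == 1000
        assert g_minus.tss == 1999

    def test_matches_brute_force_over_random_gene_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            genes = [
                GeneModel(f"G{j:02d}", "chr1", int(s), int(s) + int(rng.integers(100, 5000)), "+")
                for j, s in enumerate(rng.integers(0, 500_000, size=20))
            ]
            start = int(rng.integers(0, 500_000))
            r = region("r", "chr1", start, start + 500)
            (out,) = assign_closest([r], genes)

            def gap(g):
                return max(0, max(g.start - r.end, r.start - g.end))

            best = min(genes, key=lambda g: (gap(g), g.gene_id))
            assert out.closest_gene == best.gene_id
            assert abs(out.closest_gene_dist) == gap(best)
            best_tss = min(genes, key=lambda g: (abs(r.midpoint - g.tss), g.gene_id))
            assert out.closest_tss_gene == best_tss.gene_id

    def test_no_gene_on_chromosome_leaves_fields_undefined(self):
        (out,) = assign_closest([region("r", "chr2", 0, 100)], [GeneModel("G", "chr1", 0, 10, "+")])
        assert out.closest_gene is None and out.closest_tss_gene is None


# ---------------------------------------------------------------------------
# store


class TestRegionStore:
    def test_self_retrieval_by_own_interval(self, store, regions):
        r = regions[0]
        hits = store.query_interval(r.chrom, r.start, r.end)
        assert r.region_id in {h.region_id for h in hits}

    def test_interval_query_equals_linear_scan(self, store, regions):
        rng = np.random.default_rng(0)
        for _ in range(20):
            start = int(rng.integers(0, 900_000))
            end = start + int(rng.integers(1, 20_000))
            got = {r.region_id for r in store.query_interval("chr1", start, end)}
            expected = {
                r.region_id
                for r in regions
                if r.chrom == "chr1" and r.start < end and r.end > start
            }
            assert got == expected

    def test_gene_query_returns_exactly_linked_regions(self, store, regions):
        gene = next(r.closest_gene for r in regions if r.closest_gene)
        got = {r.region_id for r in store.query_gene(gene)}
        expected = {
            r.region_id
            for r in regions
            if gene in (r.closest_gene, r.closest_tss_gene)
        }
        assert got == expected

    def test_round_trip_reproduces_inputs(self, regions):
        links = [GeneLink(regions[0].region_id, "G1", "direct", frozenset({"liver"}))]
        plinks = [PhenotypeLink(regions[0].region_id, "HP:0000001", "hpo")]
        store = RegionStore.build(regions, links, plinks)
        out_regions, out_links, out_plinks = store.dump()
        assert sorted(r.region_id for r in out_regions) == sorted(r.region_id for r in regions)
        by_id = {r.region_id: r for r in out_regions}
        for r in regions:
            o = by_id[r.region_id]
            assert (o.chrom, o.start, o.end, o.region_type) == (r.chrom, r.start, r.end, r.region_type)
            assert o.sources == r.sources and o.tissues == r.tissues
        assert out_links == links
        assert out_plinks == plinks

    def test_dangling_link_fails_naming_ids(self, regions):
        with pytest.raises(ValueError, match="ghost"):
            RegionStore.build(regions, [GeneLink("ghost", "G1", "direct")])

    def test_empty_phenotype_table_queries_empty(self, store, regions):
        assert store.phenotype_links_for(regions[0].region_id) == []

    def test_query_details_unknown_id_not_fatal(self, store, regions):
        res = store.query_details(region_ids=[regions[0].region_id, "nope"])
        assert res["not_found"] == ["nope"]
        assert res["records"][0]["region_id"] == regions[0].region_id

    def test_query_details_interval_overlapping_nothing(self, store):
        res = store.query_details(interval=("chrX", 0, 100))
        assert res["records"] == []

    def test_query_details_vcf_equals_per_variant_queries(self, store, regions, tmp_path):
        vcf = tmp_path / "sel.vcf"
        targets = [(regions[0].chrom, regions[0].start + 1), ("chr1", 1)]
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=chr1,length=1000000>\n##contig=<ID=chr2,length=1000000>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos in targets:
                fh.write(f"{chrom}\t{pos}\t.\tA\tC\t.\t.\t.\n")
        got = {rec["region_id"] for rec in store.query_details(vcf=str(vcf))["records"]}
        expected = set()
        for chrom, pos in targets:
            expected |= {r.region_id for r in store.query_interval(chrom, pos - 1, pos)}
        assert got == expected


# ---------------------------------------------------------------------------
# extended BED


class TestBedExport:
    def test_single_region_roundtrip(self, tmp_path):
        r = region("r1", "chr1", 100, 200, constraint=0.5, sources={"s"})
        path = tmp_path / "one.bed"
        export_bed([r], path)
        line = path.read_text().strip().split("\t")
        assert line[:6] == ["chr1", "100", "200", "r1", "0.5", "."]
        (back,) = import_bed(path)
        assert (back.start, back.end, back.constraint) == (100, 200, 0.5)

    def test_export_import_export_is_byte_identical(self, regions, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        export_bed(regions, p1)
        export_bed(import_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_constraint_written_as_dot(self, tmp_path):
        path = tmp_path / "x.bed"
        export_bed([region("r", "chr1", 0, 10)], path)
        assert path.read_text().split("\t")[4] == "."

    def test_store_and_bed_agree_on_genome_coverage(self, store, genome, tmp_path):
        from regvaran.genome import covered_bases

        path = tmp_path / "cov.bed"
        store.export_bed(path)
        by_chrom = {}
        for r in import_bed(path):
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        bed_cov = sum(covered_bases(v) for v in by_chrom.values()) / genome.total_length
        assert store.genome_coverage(genome) == pytest.approx(bed_cov, abs=1e-12)
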