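"""Build a regulatory-region database from a raw source table.

Simulates a source catalog with ~5% redundant entries, normalizes it to
the five-class type vocabulary, collapses high-overlap duplicates, links
each region to its closest gene/TSS and stores everything in SQLite.
"""

from regvaran.regiondb import (
    GeneLink, RegionStore, SourceMeta, assign_closest, collapse_regions, normalize_source,
)
from regvaran.simdata import SimConfig, make_genes, make_genome, make_regions

cfg = SimConfig(seed=42, n_regions=1000, n_genes=100)
genome = make_genome(cfg)
table = make_regions(cfg, genome)

meta = SourceMeta(
    name="demo_catalog",
    columns={"chrom": "chrom", "start": "start", "end": "end", "type": "type", "tissue": "tissue"},
    coords="0-based",
)
regions, report = normalize_source(table, meta, genome)
print(f"normalized: {report.n_accepted}/{report.n_input} records accepted")

collapsed = collapse_regions(regions, reciprocal_overlap_threshold=0.8)
print(f"collapsed:  {len(regions)} -> {len(collapsed)} regions "
      "(near-duplicates merged, provenance unioned)")

genes = make_genes(cfg, genome)
linked = assign_closest(collapsed, genes)
links = [GeneLink(r.region_id, r.closest_gene, "closest_gene") for r in linked if r.closest_gene]
store = RegionStore.build(linked, links, path="demo.sqlite")

r = linked[0]
hits = store.query_interval(r.chrom, r.start, r.end)
print(f"interval query {r.chrom}:{r.start}-{r.end} -> {len(hits)} region(s), "
      f"first id {hits[0].region_id}, closest gene {hits[0].closest_gene} "
      f"at {hits[0].closest_gene_dist} bp")
print(f"genome coverage of the region set: {store.genome_coverage(genome):.1%}")
store.close()
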