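import pytest

from regvaran.regiondb import (
    GeneLink,
    RegionStore,
    SourceMeta,
    assign_closest,
    collapse_regions,
    normalize_source,
)
from regvaran.simdata import SimConfig, make_genes, make_genome, make_regions

SIM_META = SourceMeta(
    name="sim",
    columns={"chrom": "chrom", "start": "start", "end": "end", "type": "type", "tissue": "tissue"},
    coords="0-based",
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7, n_regions=400, n_genes=40, n_variants=800)


@pytest.fixture(scope="session")
def genome(sim_config):
    return make_genome(sim_config)


@pytest.fixture(scope="session")
def genes(sim_config, genome):
    return make_genes(sim_config, genome)


@pytest.fixture(scope="session")
def regions(sim_config, genome, genes):
    table = make_regions(sim_config, genome)
    normalized, report = normalize_source(table, SIM_META, genome)
    assert report.n_rejected == 0
    collapsed = collapse_regions(normalized)
    return assign_closest(collapsed, genes)


@pytest.fixture(scope="session")
def store(regions):
    links = []
    for r in regions:
        if r.closest_gene:
            links.append(GeneLink(r.region_id, r.closest_gene, "closest_gene"))
        if r.closest_tss_gene:
            links.append(GeneLink(r.region_id, r.closest_tss_gene, "closest_tss"))
    return RegionStore.build(regions, links)
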