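"""Seeded synthetic fixtures with the statistical structure the rest of
the package assumes.

Generates a small genome (with mock telomeres/centromeres as excluded
intervals), gene models, regulatory-region source tables (log-uniform
sizes between 100 and 1000 bp, a configurable fraction of planted
near-duplicates to exercise collapsing), functional-element BEDs,
partially-covering per-position score tracks with a labeled variant set
at a configured separability, per-region variant sites with a planted
depleted subset for constraint tests, and trio VCF+PED files with
Hardy-Weinberg background genotypes and scenario-specific spiked
variants. Every generator is byte-deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from regvaran.genome import GenomeModel
from regvaran.regiondb import GeneModel, RegulatoryRegion
from regvaran.region_eval import PositionTrack

BASES = np.array(list("ACGT"))
REGION_TYPE_WEIGHTS = {
    # rough relative abundance of the five classes in regulatory catalogs:
    # enhancers dominate, then promoters; the rest are minor strata
    "enhancer": 0.55,
    "promoter": 0.25,
    "bivalent": 0.08,
    "insulator": 0.07,
    "silencer": 0.05,
}


@dataclass
class SimConfig:
    """Study-condition defaults for all generators (desk scale)."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    telomere_bp: int = 10_000
    centromere_bp: int = 50_000
    n_regions: int = 2000
    region_size_bounds: tuple[int, int] = (100, 1000)  # log-uniform
    duplicate_fraction: float = 0.05  # planted high-overlap duplicates
    n_genes: int = 200
    n_variants: int = 5000  # trio background variants
    common_fraction: float = 0.3  # AF mixture: common vs rare
    common_af: tuple[float, float] = (0.05, 0.5)
    rare_af: tuple[float, float] = (1e-4, 9e-3)
    track_coverage: float = 0.15  # fraction of genome positions covered per track
    target_auc: float = 0.85  # separability of the labeled score distributions
    n_positive: int = 72
    n_negative: int = 725  # 1:10 class ratio
    variant_rate: float = 0.05  # expected variants per bp for constraint counts
    depletion_factor: float = 0.2  # rate multiplier for the constrained subset
    depleted_fraction: float = 0.02

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed + 1) * 100_003 + salt)


# ---------------------------------------------------------------------------
# Genome and genes


def make_genome(config: SimConfig, with_sequence: bool = False):
    """GenomeModel with telomeric/centromeric exclusions; optional sequence."""
    excluded = {}
    for chrom, length in config.chrom_lengths.items():
        # clamp so small test chromosomes still get valid exclusions
        tel = min(config.telomere_bp, length // 20)
        cen = min(config.centromere_bp, length // 10)
        mid = length // 2
        ivs = [(0, tel), (mid - cen // 2, mid + cen // 2), (length - tel, length)]
        excluded[chrom] = [(s, e) for s, e in ivs if e > s]
    genome = GenomeModel(dict(config.chrom_lengths), excluded)
    if not with_sequence:
        return genome
    rng = config.rng(1)
    sequences = {
        chrom: "".join(BASES[rng.integers(0, 4, size=length)])
        for chrom, length in config.chrom_lengths.items()
    }
    return genome, sequences


def make_genes(config: SimConfig, genome: GenomeModel) -> list[GeneModel]:
    """Non-overlapping gene spans, half on each strand."""
    rng = config.rng(2)
    genes = []
    chroms = genome.chromosomes
    per_chrom = config.n_genes // len(chroms)
    gid = 0
    for chrom in chroms:
        length = genome.lengths[chrom]
        # evenly spaced slots keep genes disjoint and deterministic
        slot = length // (per_chrom + 1)
        for k in range(per_chrom):
            anchor = (k + 1) * slot
            size = int(rng.integers(2000, 20_000))
            start = max(0, anchor - size // 2)
            end = min(length, start + size)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"GENE{gid:04d}", chrom, start, end, strand))
            gid += 1
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tbiotype\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# Region tables


def make_regions(config: SimConfig, genome: GenomeModel, source: str = "sim") -> "pd.DataFrame":
    """Raw region source table (0-based half-open) with planted duplicates.

    Region sizes are log-uniform within ``region_size_bounds``; a
    ``duplicate_fraction`` of regions is re-emitted with a small jitter so
    that each duplicate has high reciprocal overlap with its original.
    """
    import pandas as pd

    rng = config.rng(3)
    types = list(REGION_TYPE_WEIGHTS)
    probs = np.array(list(REGION_TYPE_WEIGHTS.values()))
    chroms = genome.chromosomes
    lo, hi = config.region_size_bounds

    rows = []
    n_primary = int(round(config.n_regions / (1 + config.duplicate_fraction)))
    for _ in range(n_primary):
        chrom = chroms[rng.integers(0, len(chroms))]
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        start = int(rng.integers(0, genome.lengths[chrom] - size))
        rtype = types[rng.choice(len(types), p=probs)]
        tissue = ["brain", "liver", "heart", "kidney"][rng.integers(0, 4)]
        rows.append((chrom, start, start + size, rtype, tissue))

    n_dup = config.n_regions - n_primary
    dup_idx = rng.choice(n_primary, size=n_dup, replace=False)
    for i in dup_idx:
        chrom, start, end, rtype, tissue = rows[i]
        size = end - start
        jitter = int(rng.integers(0, max(size // 20, 1)))  # <=5% shift: RO >= 0.9
        rows.append((chrom, start + jitter, end + jitter, rtype, tissue))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "tissue"])
    df["source"] = source
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def make_functional_elements(
    config: SimConfig,
    genome: GenomeModel,
    regions: Sequence[RegulatoryRegion],
    hit_fraction: float = 0.3,
) -> dict[str, list[tuple[str, int, int]]]:
    """TFBS/DNase/UCNE interval sets; each covers ``hit_fraction`` of the
    regions (a small element inside the region) plus random background."""
    rng = config.rng(4)
    out: dict[str, list[tuple[str, int, int]]] = {}
    for cls in ("TFBS", "DNase", "UCNE"):
        ivs = []
        chosen = rng.choice(len(regions), size=int(hit_fraction * len(regions)), replace=False)
        for i in chosen:
            r = regions[i]
            width = max(min(20, r.length), 1)
            s = int(rng.integers(r.start, max(r.end - width, r.start) + 1))
            ivs.append((r.chrom, s, s + width))
        for _ in range(100):  # background elements off the regions
            chrom = genome.chromosomes[rng.integers(0, len(genome.chromosomes))]
            s = int(rng.integers(0, genome.lengths[chrom] - 50))
            ivs.append((chrom, s, s + 50))
        out[cls] = sorted(ivs)
    return out


def make_covariate_features(
    config: SimConfig, genome: GenomeModel, block_bp: int = 2000, coverage: float = 0.08
) -> dict[str, list[tuple[str, int, int]]]:
    """Random segdup/LCR/exon interval sets, each covering ~``coverage``
    of the genome in fixed-size blocks, for the constraint covariates."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    for k, name in enumerate(("segdup", "lcr", "exon")):
        rng = config.rng(20 + k)
        ivs = []
        for chrom in genome.chromosomes:
            n_blocks = int(coverage * genome.lengths[chrom] / block_bp)
            starts = rng.integers(0, genome.lengths[chrom] - block_bp, size=n_blocks)
            ivs.extend((chrom, int(s), int(s) + block_bp) for s in sorted(starts))
        out[name] = ivs
    return out


# ---------------------------------------------------------------------------
# Score tracks and labeled sets


def make_labeled_set(config: SimConfig, genome: GenomeModel) -> "pd.DataFrame":
    """Labeled variant table (chrom, pos 1-based, ref, alt, label)."""
    import pandas as pd

    rng = config.rng(5)
    n = config.n_positive + config.n_negative
    chroms = genome.chromosomes
    recs = []
    used = set()
    while len(recs) < n:
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(1, genome.lengths[chrom] + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(4, size=2, replace=False)
        recs.append((chrom, pos, BASES[ref], BASES[alt]))
    df = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    df["label"] = [1] * config.n_positive + [0] * config.n_negative
    return df


def make_score_tracks(
    config: SimConfig,
    genome: GenomeModel,
    labeled: "pd.DataFrame",
    score_names: Sequence[str] = ("scoreA", "scoreB", "scoreC"),
) -> dict[str, PositionTrack]:
    """Per-score tracks covering labeled positions plus random background.

    Positive-labeled positions draw from N(shift, 1) and negatives from
    N(0, 1) with shift chosen so the expected AUC is ``target_auc``
    (AUC = Phi(shift / sqrt 2)); background positions cover
    ``track_coverage`` of the genome.
    """
    shift = float(np.sqrt(2.0) * sps.norm.ppf(config.target_auc))
    tracks = {}
    for k, name in enumerate(score_names):
        rng = config.rng(6 + k)
        recs = []
        for row in labeled.itertuples(index=False):
            mu = shift if row.label == 1 else 0.0
            recs.append((str(row.chrom), int(row.pos), float(rng.normal(mu, 1.0))))
        labeled_pos = {(str(r.chrom), int(r.pos)) for r in labeled.itertuples(index=False)}
        for chrom in genome.chromosomes:
            n_bg = int(config.track_coverage * genome.lengths[chrom]) - sum(
                1 for c, _ in labeled_pos if c == chrom
            )
            bg = rng.choice(genome.lengths[chrom], size=max(n_bg, 0), replace=False) + 1
            for pos in bg:
                if (chrom, int(pos)) not in labeled_pos:
                    recs.append((chrom, int(pos), float(rng.normal(0.0, 1.0))))
        tracks[name] = PositionTrack.from_records(recs)
    return tracks


def write_track_tsv(track: PositionTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tvalue\n")
        for chrom in sorted(track.positions):
            for pos, val in zip(track.positions[chrom], track.values[chrom]):
                fh.write(f"{chrom}\t{pos + 1}\t{val:.6g}\n")


# ---------------------------------------------------------------------------
# Variant sites for constraint


def make_variant_sites(
    config: SimConfig,
    regions: Sequence[RegulatoryRegion],
    depleted_ids: "set[str] | None" = None,
) -> list[tuple[str, int]]:
    """Poisson variant sites per region: rate*length expected sites, with
    the depleted subset's rate multiplied by ``depletion_factor``.

    Returns (chrom, 1-based position) pairs; positions are unique within
    each region.
    """
    rng = config.rng(9)
    depleted_ids = depleted_ids or set()
    sites = []
    for r in regions:
        lam = config.variant_rate * r.length
        if r.region_id in depleted_ids:
            lam *= config.depletion_factor
        n = min(int(rng.poisson(lam)), r.length)
        offsets = rng.choice(r.length, size=n, replace=False)
        for off in offsets:
            sites.append((r.chrom, r.start + int(off) + 1))
    return sorted(sites)


def pick_depleted(config: SimConfig, regions: Sequence[RegulatoryRegion]) -> set[str]:
    rng = config.rng(10)
    n = max(int(config.depleted_fraction * len(regions)), 1)
    idx = rng.choice(len(regions), size=n, replace=False)
    return {regions[i].region_id for i in idx}


# ---------------------------------------------------------------------------
# Trio VCF


def _random_allele_pair(rng, af: float) -> tuple[int, int]:
    return (int(rng.random() < af), int(rng.random() < af))


def _transmit(rng, father: tuple[int, int], mother: tuple[int, int]) -> tuple[int, int]:
    return (father[rng.integers(0, 2)], mother[rng.integers(0, 2)])


def make_trio_vcf(
    config: SimConfig,
    genome: GenomeModel,
    scenario: str = "null",
    out_vcf: str | Path = "trio.vcf",
    out_ped: str | Path | None = None,
    spike: "Sequence[tuple[str, int, str, str]] | None" = None,
    samples: tuple[str, str, str] = ("proband", "father", "mother"),
) -> "list[tuple[str, int, str, str]]":
    """Write a trio VCF (+PED) with HWE background and spiked variants.

    Scenarios: ``recessive`` (proband 1/1, parents 0/1), ``dominant``
    (proband 0/1, parents 0/0), ``comphet`` (two proband-het variants,
    one per parent) and ``null`` (no spike). ``spike`` positions
    (chrom, pos, ref, alt) override the default spike placement; spiked
    records carry AF below 1%. Returns the spiked variant keys.
    """
    if scenario not in ("recessive", "dominant", "comphet", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = config.rng(11)
    proband, father, mother = samples

    records = []  # (chrom, pos, ref, alt, af, gt_proband, gt_father, gt_mother)
    used: set[tuple[str, int]] = set()
    chroms = genome.chromosomes
    while len(records) < config.n_variants:
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(1, genome.lengths[chrom] + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        if rng.random() < config.common_fraction:
            af = float(rng.uniform(*config.common_af))
        else:
            af = float(rng.uniform(*config.rare_af))
        ref, alt = (BASES[i] for i in rng.choice(4, size=2, replace=False))
        gt_f = _random_allele_pair(rng, af)
        gt_m = _random_allele_pair(rng, af)
        gt_p = _transmit(rng, gt_f, gt_m)
        records.append((chrom, pos, str(ref), str(alt), af, gt_p, gt_f, gt_m))

    spiked_keys: list[tuple[str, int, str, str]] = []
    if scenario != "null":
        n_spike = 2 if scenario == "comphet" else 1
        spikes = list(spike) if spike else []
        while len(spikes) < n_spike:
            chrom = chroms[0]
            pos = int(rng.integers(1, genome.lengths[chrom] + 1))
            if (chrom, pos) in used:
                continue
            ref, alt = (str(BASES[i]) for i in rng.choice(4, size=2, replace=False))
            spikes.append((chrom, pos, ref, alt))
        gts = {
            "recessive": [((1, 1), (0, 1), (0, 1))],
            "dominant": [((0, 1), (0, 0), (0, 0))],
            "comphet": [((0, 1), (0, 1), (0, 0)), ((0, 1), (0, 0), (0, 1))],
        }[scenario]
        for (chrom, pos, ref, alt), (gt_p, gt_f, gt_m) in zip(spikes, gts):
            used.add((chrom, pos))
            records.append((chrom, pos, ref, alt, 0.001, gt_p, gt_f, gt_m))
            spiked_keys.append((chrom, pos, ref, alt))

    records.sort(key=lambda r: (r[0], r[1]))
    with open(out_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{proband}\t{father}\t{mother}\n")
        for chrom, pos, ref, alt, af, gt_p, gt_f, gt_m in records:
            gts = "\t".join(f"{a}/{b}" for a, b in (gt_p, gt_f, gt_m))
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af:.6g}\tGT\t{gts}\n")

    if out_ped is not None:
        with open(out_ped, "w") as fh:
            fh.write(f"FAM1\t{proband}\t{father}\t{mother}\t1\t2\n")
            fh.write(f"FAM1\t{father}\t0\t0\t1\t1\n")
            fh.write(f"FAM1\t{mother}\t0\t0\t2\t1\n")
    return spiked_keys
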