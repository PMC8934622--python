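"""Gene percentiles, HPO-based filtering, trio segregation and compound hets."""

import itertools

import numpy as np
import pytest

from regvaran.prioritize import (
    AnnotatedVariant,
    GeneRankTable,
    Pedigree,
    compound_het_pairs,
    gene_percentile,
    hpo_prioritize,
    segregation_filter,
)

TRIO = ("kid", "dad", "mom")


def variant(chrom="chr1", pos=100, ref="A", alt="C", level=3, genes=(),
            gts=None, coding=False):
    return AnnotatedVariant(
        chrom, pos, ref, alt, level, set(genes),
        genotypes=gts or {}, coding=coding,
    )


class TestGenePercentile:
    def test_unique_maximum_gets_highest_percentile(self):
        table = GeneRankTable({f"G{i}": float(i) for i in range(10)})
        assert table.percentile("G9") == max(table.percentile(g) for g in table.zscores)
        assert table.percentile("G9") == pytest.approx((9 + 0.5) / 10)

    def test_midrank_for_fifth_largest_of_hundred(self):
        table = GeneRankTable({f"G{i:03d}": float(i) for i in range(100)})
        assert table.percentile("G095") == pytest.approx(0.955)

    def test_tied_zscores_share_percentile(self):
        table = GeneRankTable({"A": 1.0, "B": 1.0, "C": 0.0})
        assert table.percentile("A") == table.percentile("B")

    def test_absent_gene_is_undefined_not_guessed(self):
        table = GeneRankTable({"A": 1.0})
        assert gene_percentile(table, "missing") is None
        with pytest.raises(KeyError):
            table.percentile("missing")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            GeneRankTable({})


class TestHpoPrioritize:
    TABLE = GeneRankTable({f"G{i:03d}": float(i) for i in range(100)})

    def test_high_level_high_percentile_kept(self):
        out = hpo_prioritize([variant(level=3, genes={"G099"})], self.TABLE, 3, 0.95)
        assert len(out) == 1 and out[0][1] == "G099"

    def test_low_percentile_gene_dropped(self):
        out = hpo_prioritize([variant(level=3, genes={"G050"})], self.TABLE, 3, 0.95)
        assert out == []

    def test_low_level_dropped(self):
        out = hpo_prioritize([variant(level=2, genes={"G099"})], self.TABLE, 3, 0.95)
        assert out == []

    def test_matches_filter_and_sort_oracle(self):
        rng = np.random.default_rng(0)
        variants = []
        for i in range(50):
            genes = {f"G{int(g):03d}" for g in rng.integers(0, 100, size=rng.integers(1, 4))}
            variants.append(
                variant(pos=int(rng.integers(1, 10_000)), level=int(rng.integers(0, 5)),
                        genes=genes)
            )
        got = hpo_prioritize(variants, self.TABLE, 2, 0.90)
        # independent re-implementation
        expected = []
        for v in variants:
            if v.level < 2:
                continue
            ok = [g for g in v.all_genes if g in self.TABLE.zscores
                  and self.TABLE.percentile(g) >= 0.90]
            if ok:
                z = max(self.TABLE.zscores[g] for g in ok)
                expected.append((v.key, z))
        expected.sort(key=lambda t: (-t[1], t[0]))
        assert [(v.key, z) for v, _, z in got] == expected

    def test_tightening_thresholds_never_adds_candidates(self):
        rng = np.random.default_rng(1)
        variants = [
            variant(pos=i, level=int(rng.integers(0, 5)),
                    genes={f"G{int(rng.integers(0, 100)):03d}"})
            for i in range(100)
        ]
        counts = {}
        for lvl in (1, 2, 3, 4):
            for pct in (0.5, 0.9, 0.95, 0.99):
                counts[(lvl, pct)] = len(hpo_prioritize(variants, self.TABLE, lvl, pct))
        # monotone along each axis
        for pct in (0.5, 0.9, 0.95, 0.99):
            seq = [counts[(l, pct)] for l in (1, 2, 3, 4)]
            assert seq == sorted(seq, reverse=True)
        for lvl in (1, 2, 3, 4):
            seq = [counts[(lvl, p)] for p in (0.5, 0.9, 0.95, 0.99)]
            assert seq == sorted(seq, reverse=True)


class TestSegregation:
    def gt(self, kid, dad, mom):
        return {"kid": kid, "dad": dad, "mom": mom}

    def test_classic_recessive_trio_passes(self):
        v = variant(gts=self.gt((1, 1), (0, 1), (0, 1)))
        assert segregation_filter(v, TRIO, "recessive")

    def test_hom_alt_parent_fails_recessive(self):
        v = variant(gts=self.gt((1, 1), (1, 1), (0, 1)))
        assert not segregation_filter(v, TRIO, "recessive")

    def test_dominant_de_novo_pattern(self):
        assert segregation_filter(variant(gts=self.gt((0, 1), (0, 0), (0, 0))), TRIO, "dominant")
        assert not segregation_filter(variant(gts=self.gt((0, 1), (0, 1), (0, 0))), TRIO, "dominant")

    def test_missing_genotype_fails_safe(self):
        v = variant(gts={"kid": (1, 1), "dad": (0, 1)})
        assert not segregation_filter(v, TRIO, "recessive")
        v2 = variant(gts=self.gt((1, 1), (None, None), (0, 1)))
        assert not segregation_filter(v2, TRIO, "recessive")

    def test_simulated_trios_match_rule_oracle(self):
        rng = np.random.default_rng(2)
        # trios drawn under the recessive model always pass
        for _ in range(200):
            v = variant(gts=self.gt((1, 1), (0, 1), (0, 1)))
            assert segregation_filter(v, TRIO, "recessive")
        # random-mating trios: pass rate equals the direct genotype rule
        n_pass_pkg = n_pass_oracle = 0
        for _ in range(200):
            dad = tuple(int(rng.random() < 0.4) for _ in range(2))
            mom = tuple(int(rng.random() < 0.4) for _ in range(2))
            kid = (dad[rng.integers(0, 2)], mom[rng.integers(0, 2)])
            v = variant(gts=self.gt(kid, dad, mom))
            n_pass_pkg += segregation_filter(v, TRIO, "recessive")
            n_pass_oracle += (sum(kid) == 2 and sum(dad) == 1 and sum(mom) == 1)
        assert n_pass_pkg == n_pass_oracle


class TestCompoundHet:
    def hets(self, dad_carries, mom_carries):
        dad = (0, 1) if dad_carries else (0, 0)
        mom = (0, 1) if mom_carries else (0, 0)
        return {"kid": (0, 1), "dad": dad, "mom": mom}

    def test_trans_pair_detected(self):
        v1 = variant(pos=100, genes={"G"}, gts=self.hets(True, False))
        v2 = variant(pos=200, genes={"G"}, gts=self.hets(False, True))
        pairs = compound_het_pairs([v1, v2], TRIO)
        assert len(pairs) == 1
        assert pairs[0].phase == "trans" and pairs[0].gene == "G"

    def test_cis_pair_excluded(self):
        v1 = variant(pos=100, genes={"G"}, gts=self.hets(True, False))
        v2 = variant(pos=200, genes={"G"}, gts=self.hets(True, False))
        assert compound_het_pairs([v1, v2], TRIO) == []

    def test_ambiguous_phase_kept_and_flagged(self):
        v1 = variant(pos=100, genes={"G"}, gts=self.hets(True, True))
        v2 = variant(pos=200, genes={"G"}, gts=self.hets(True, True))
        pairs = compound_het_pairs([v1, v2], TRIO)
        assert len(pairs) == 1 and pairs[0].phase == "ambiguous"

    def test_never_pairs_across_genes(self):
        v1 = variant(pos=100, genes={"G1"}, gts=self.hets(True, False))
        v2 = variant(pos=200, genes={"G2"}, gts=self.hets(False, True))
        assert compound_het_pairs([v1, v2], TRIO) == []

    def test_composition_classification(self):
        v1 = variant(pos=100, genes={"G"}, gts=self.hets(True, False), coding=True)
        v2 = variant(pos=200, genes={"G"}, gts=self.hets(False, True))
        (pair,) = compound_het_pairs([v1, v2], TRIO)
        assert pair.composition == "coding+regulatory"

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        variants = []
        for i in range(30):
            gene = f"G{int(rng.integers(0, 5))}"
            kid = tuple(int(x) for x in rng.integers(0, 2, 2))
            dad = tuple(int(x) for x in rng.integers(0, 2, 2))
            mom = tuple(int(x) for x in rng.integers(0, 2, 2))
            variants.append(
                variant(pos=100 + i, genes={gene},
                        gts={"kid": kid, "dad": dad, "mom": mom},
                        coding=bool(rng.random() < 0.5))
            )
        got = {(p.gene, p.v1.key, p.v2.key, p.phase) for p in compound_het_pairs(variants, TRIO)}

        def origin(v):
            if sorted(v.genotypes["kid"]) != [0, 1]:
                return None
            d = sum(v.genotypes["dad"]) > 0
            m = sum(v.genotypes["mom"]) > 0
            return {(True, False): "P", (False, True): "M", (True, True): "?"}.get((d, m))

        expected = set()
        for v1, v2 in itertools.combinations(variants, 2):
            common = v1.all_genes & v2.all_genes
            o1, o2 = origin(v1), origin(v2)
            if not common or o1 is None or o2 is None:
                continue
            if "?" in (o1, o2):
                phase = "ambiguous"
            elif o1 != o2:
                phase = "trans"
            else:
                continue
            a, b = sorted([v1, v2], key=lambda v: v.key)
            for g in common:
                expected.add((g, a.key, b.key, phase))
        assert got == expected


class TestPedigree:
    def test_ped_roundtrip_and_trio_detection(self, tmp_path):
        ped = tmp_path / "fam.ped"
        ped.write_text(
            "FAM1\tkid\tdad\tmom\t1\t2\n"
            "FAM1\tdad\t0\t0\t1\t1\n"
            "FAM1\tmom\t0\t0\t2\t1\n"
            "FAM2\tuncle\t0\t0\t1\t1\n"
        )
        p = Pedigree.from_ped(ped)
        assert p.trios() == [("kid", "dad", "mom")]
        assert p.samples["kid"].affected
        assert not p.samples["dad"].affected
        assert p.samples["mom"].sex == "female"


class TestSpikeInRecovery:
    def test_unique_spiked_variant_is_sole_candidate(self, tmp_path, genome, regions, store, sim_config):
        """A variant meeting level-3 criteria on the unique high-Z gene is
        the only candidate returned at (level >= 3, percentile >= 0.95)."""
        from regvaran.region_eval import PositionTrack
        from regvaran.simdata import make_trio_vcf
        from regvaran.varan import LevelConfig, annotate_vcf
        from regvaran.prioritize import read_annotated_vcf

        target = next(r for r in regions if r.closest_gene)
        pos = target.start + target.length // 2 + 1
        spike = [(target.chrom, pos, "A", "T")]
        vcf = tmp_path / "bg.vcf"
        make_trio_vcf(sim_config, genome, "recessive", vcf, spike=spike)

        fe = {"TFBS": [(target.chrom, pos - 1, pos)]}
        track = PositionTrack.from_records([(target.chrom, pos, 10.0)])
        cfg = LevelConfig(score_thresholds={"s": 5.0})
        out = tmp_path / "bg_ann.vcf"
        annotate_vcf(vcf, out, store, fe, {"s": track}, cfg)

        table = {f"X{i:03d}": float(-i) for i in range(1, 200)}
        table[target.closest_gene] = 50.0  # unique high-Z gene
        ranked = hpo_prioritize(read_annotated_vcf(out), GeneRankTable(table), 3, 0.95)
        assert len(ranked) == 1
        v, gene, _ = ranked[0]
        assert (v.chrom, v.pos) == (target.chrom, pos)
        assert gene == target.closest_gene
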