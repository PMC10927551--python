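"""Unit and property tests for the karyotype-evolution generator."""

import numpy as np
import pytest
from scipy import stats as sps

from paleokaryo.genome import GenomeMap
from paleokaryo.simulate import (
    EvolutionScenario,
    ancestral_family_lists,
    apply_attrition,
    apply_fission,
    apply_fusion,
    apply_wgd,
    artificial_split,
    descent_of,
    emit_hit_table,
    empty_chromosomes,
    make_ancestral_genome,
    run_scenario,
    simulate_post1R_fusion_null,
    speciate,
)


class TestMakeAncestralGenome:
    def test_smallest_case(self):
        g = make_ancestral_genome(1, 3, 0)
        assert g.n_chromosomes == 1 and len(g) == 3
        assert len({x.family_id for x in g}) == 3
        assert all(x.family_id == x.gene_id for x in g)

    def test_gene_count_product(self):
        g = make_ancestral_genome(17, 300, 42)
        assert g.n_chromosomes == 17 and len(g) == 17 * 300

    @pytest.mark.parametrize("n_chr,n_genes", [(2, 0), (0, 5), (-1, 3)])
    def test_degenerate_rejected(self, n_chr, n_genes):
        with pytest.raises(ValueError):
            make_ancestral_genome(n_chr, n_genes, 0)


class TestWGD:
    @pytest.mark.parametrize("mult", [2, 3])
    def test_multiplies_chromosomes_and_families(self, mult):
        g = make_ancestral_genome(2, 5, 0)
        d = apply_wgd(g, mult, "auto", 0)
        assert d.n_chromosomes == 2 * mult
        assert all(n == mult for n in d.family_multiset().values())

    def test_bad_multiplicity(self):
        with pytest.raises(ValueError):
            apply_wgd(make_ancestral_genome(1, 2, 0), 4, "auto", 0)

    def test_empty_genome_rejected(self):
        g = make_ancestral_genome(1, 1, 0)
        g = apply_attrition(g, loss_rate=1.0, seed=0)
        with pytest.raises(ValueError):
            apply_wgd(g, 2, "auto", 0)

    def test_allo_mode_biases_subgenome_loss(self):
        g = make_ancestral_genome(4, 400, 0)
        d = apply_wgd(g, 2, "allo", 3, allo_extra_loss=0.15)
        n_a = sum(len(d.genes_on(c)) for c in d.chromosomes if c.endswith("~a"))
        n_b = sum(len(d.genes_on(c)) for c in d.chromosomes if c.endswith("~b"))
        assert n_a == 1600  # untouched subgenome
        # kept fraction of the b subgenome within a 99.9% binomial band
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 1600, 0.85)
        assert lo <= n_b <= hi

    def test_subgenome_tags_in_descent(self):
        g = make_ancestral_genome(1, 2, 0)
        d = apply_wgd(g, 3, "auto", 0)
        assert descent_of(d, "AC01~c") == (("AC01", "c"),)


class TestFusionFission:
    def test_fusion_concatenates(self):
        g = make_ancestral_genome(2, 10, 0)
        g2 = apply_fission(g, "AC02", 5)
        fused = apply_fusion(g2, "AC01", "AC02:1")
        assert len(fused.genes_on("AC01+AC02:1")) == 15
        assert fused.n_chromosomes == g2.n_chromosomes - 1

    def test_fusion_self_and_unknown(self):
        g = make_ancestral_genome(2, 3, 0)
        with pytest.raises(ValueError):
            apply_fusion(g, "AC01", "AC01")
        with pytest.raises(KeyError):
            apply_fusion(g, "AC01", "nope")

    def test_fission_sizes_and_bounds(self):
        g = make_ancestral_genome(1, 100, 0)
        s = apply_fission(g, "AC01", 1)
        assert len(s.genes_on("AC01:1")) == 1 and len(s.genes_on("AC01:2")) == 99
        for bad in (0, 100, -3):
            with pytest.raises(ValueError):
                apply_fission(g, "AC01", bad)

    @pytest.mark.parametrize("op", ["fusion", "fission"])
    def test_family_multiset_conserved(self, op):
        g = make_ancestral_genome(3, 20, 0)
        before = g.family_multiset()
        if op == "fusion":
            after = apply_fusion(g, "AC01", "AC03").family_multiset()
        else:
            after = apply_fission(g, "AC02", 7).family_multiset()
        assert before == after


class TestAttrition:
    def test_zero_rates_identity(self):
        g = make_ancestral_genome(2, 30, 0)
        out = apply_attrition(g, 0, 0, 0, seed=5)
        assert out.family_multiset() == g.family_multiset()
        assert [x.gene_id for x in out] == [x.gene_id for x in g]

    def test_total_loss_keeps_flagged_empty_chromosomes(self):
        g = make_ancestral_genome(3, 10, 0)
        out = apply_attrition(g, loss_rate=1.0, seed=1)
        assert len(out) == 0
        assert set(empty_chromosomes(out)) == set(g.chromosomes)

    def test_retained_count_within_binomial_band(self):
        g = make_ancestral_genome(10, 1000, 0)
        out = apply_attrition(g, loss_rate=0.3, seed=11)
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 10_000, 0.7)
        assert lo <= len(out) <= hi

    def test_rates_validated(self):
        g = make_ancestral_genome(1, 2, 0)
        with pytest.raises(ValueError):
            apply_attrition(g, loss_rate=1.5)
        with pytest.raises(ValueError):
            apply_attrition(g, ssd_rate=-0.1)

    def test_translocation_preserves_families_and_moves_genes(self):
        g = make_ancestral_genome(4, 200, 0)
        out = apply_attrition(g, transloc_rate=0.1, seed=2)
        assert out.family_multiset() == g.family_multiset()
        moved = sum(
            1
            for c in out.chromosomes
            for x in out.genes_on(c)
            if not x.family_id.startswith(c.split("~")[0].split("+")[0])
        )
        assert moved > 0

    def test_ssd_adds_copies_same_family(self):
        g = make_ancestral_genome(2, 500, 0)
        out = apply_attrition(g, ssd_rate=0.1, seed=3)
        counts = out.family_multiset()
        assert len(out) > len(g)
        assert set(counts) == set(g.family_multiset())


class TestSpeciate:
    def test_zero_attrition_identical_content(self):
        g = make_ancestral_genome(2, 10, 0)
        a, b = speciate(g, ["x", "y"], seed=0)
        assert a.species == "x" and b.species == "y"
        assert {c: [x.gene_id for x in a.genes_on(c)] for c in a.chromosomes} == {
            c: [x.gene_id for x in b.genes_on(c)] for c in b.chromosomes
        }

    def test_single_name_rejected(self):
        with pytest.raises(ValueError):
            speciate(make_ancestral_genome(1, 2, 0), ["solo"])

    def test_independent_attrition(self):
        g = make_ancestral_genome(2, 300, 0)
        a, b = speciate(g, ["x", "y"], loss_rate=0.3, seed=9)
        assert len(a) != len(g) and len(b) != len(g)
        assert {x.gene_id for x in a} != {x.gene_id for x in b}


class TestArtificialSplit:
    def test_even_and_odd_midpoints(self):
        g = make_ancestral_genome(1, 100, 0)
        l, r = artificial_split(g, "AC01")
        assert len(l) == len(r) == 50
        g7 = make_ancestral_genome(1, 7, 0)
        l7, r7 = artificial_split(g7, "AC01")
        assert (len(l7), len(r7)) == (3, 4)

    def test_halves_partition_without_mutation(self):
        g = make_ancestral_genome(1, 30, 0)
        l, r = artificial_split(g, "AC01")
        assert {x.gene_id for x in l} & {x.gene_id for x in r} == set()
        assert {x.gene_id for x in l} | {x.gene_id for x in r} == {
            x.gene_id for x in g
        }
        assert len(g.genes_on("AC01")) == 30

    def test_too_small_rejected(self):
        g = make_ancestral_genome(1, 1, 0)
        with pytest.raises(ValueError):
            artificial_split(g, "AC01")


class TestHitTable:
    @staticmethod
    def _two_genomes(n_chr=1, n_genes=1, loss=0.0, seed=0):
        g = make_ancestral_genome(n_chr, n_genes, seed)
        return speciate(g, ["sa", "sb"], loss_rate=loss, seed=seed)

    def test_single_family_reciprocal_rows(self):
        a, b = self._two_genomes()
        hits = emit_hit_table([a, b], score_noise_sd=0.0, seed=0)
        assert len(hits) == 2
        assert set(zip(hits["qseqid"], hits["sseqid"])) == {
            ("sa:AC01g0000", "sb:AC01g0000"),
            ("sb:AC01g0000", "sa:AC01g0000"),
        }
        assert hits["bitscore"].nunique() == 1

    def test_no_offtarget_means_family_hits_only(self):
        a, b = self._two_genomes(2, 50)
        hits = emit_hit_table([a, b], offtarget_rate=0.0, seed=1)
        fam = lambda q: q.split(":", 1)[1]
        assert all(fam(q) == fam(s) for q, s in zip(hits["qseqid"], hits["sseqid"]))

    def test_offtarget_count_within_binomial_band(self):
        a, b = self._two_genomes(2, 50)
        hits = emit_hit_table([a, b], offtarget_rate=0.01, seed=5)
        fam = lambda q: q.split(":", 1)[1]
        spurious = sum(
            fam(q) != fam(s) for q, s in zip(hits["qseqid"], hits["sseqid"])
        )
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 100, 0.01)
        assert lo <= spurious <= hi

    def test_evalue_monotone_in_score(self):
        a, b = self._two_genomes(2, 40)
        hits = emit_hit_table([a, b], seed=2)
        s = hits.sort_values("bitscore")
        assert (np.diff(s["evalue"].values) <= 1e-12).all()

    def test_negative_sd_rejected(self):
        a, b = self._two_genomes()
        with pytest.raises(ValueError):
            emit_hit_table([a, b], score_noise_sd=-1.0)


class TestScenario:
    def test_validation(self):
        with pytest.raises(ValueError):
            EvolutionScenario(0, 10)
        with pytest.raises(ValueError):
            EvolutionScenario(1, 10, [{"type": "mystery"}])
        with pytest.raises(ValueError):
            EvolutionScenario(1, 10, [{"type": "wgd", "multiplicity": 5}])
        with pytest.raises(ValueError):
            EvolutionScenario(1, 10, [{"type": "attrition", "loss_rate": 2.0}])

    def test_seed_determinism(self):
        scn = dict(
            n_ancestral_chromosomes=4,
            genes_per_chromosome=50,
            events=[
                {"type": "wgd", "multiplicity": 2},
                {"type": "fusions", "n": 2},
                {"type": "speciate", "names": ["a", "b"], "loss_rate": 0.3,
                 "transloc_rate": 0.02, "ssd_rate": 0.02},
            ],
            seed=13,
        )
        r1 = run_scenario(EvolutionScenario(**scn))
        r2 = run_scenario(EvolutionScenario(**scn))
        for sp in r1.genomes:
            assert [
                (x.gene_id, x.chromosome) for x in r1.genomes[sp]
            ] == [(x.gene_id, x.chromosome) for x in r2.genomes[sp]]

    def test_random_fusions_join_distinct_acs(self):
        scn = EvolutionScenario(
            6, 30,
            [{"type": "wgd", "multiplicity": 2}, {"type": "fusions", "n": 3}],
            seed=5,
        )
        res = run_scenario(scn)
        g = res.genomes["__main__"]
        for chrom in g.chromosomes:
            acs = [ac for ac, _ in descent_of(g, chrom)]
            assert len(acs) == len(set(acs))

    def test_truth_ohnolog_and_ortholog_pairs(self):
        scn = EvolutionScenario(
            2, 40,
            [
                {"type": "wgd", "multiplicity": 2},
                {"type": "speciate", "names": ["a", "b"], "loss_rate": 0.3},
            ],
            seed=3,
        )
        res = run_scenario(scn)
        assert res.true_ohnolog_pairs("a") == [
            ("AC01~a", "AC01~b"), ("AC02~a", "AC02~b")
        ]
        assert res.true_ortholog_pairs("a", "b") == [
            (c, c) for c in sorted(res.genomes["a"].chromosomes)
        ]


class TestFusionNull:
    def test_zero_fusions(self):
        assert simulate_post1R_fusion_null(5, 0, 100, 0) == 0.0

    def test_exhaustive_two_ac_case(self):
        # all perfect matchings of the 4 post-WGD chromosomes: 3; two of
        # them pair the copies of AC1 with the copies of AC2 -> 2/3
        expected = 2 / 3
        frac = simulate_post1R_fusion_null(2, 2, 20_000, 1)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(frac - expected) < 3 * se

    @pytest.mark.parametrize("n_ac,n_fus", [(17, 8), (3, 1), (10, 10)])
    def test_fraction_in_unit_interval(self, n_ac, n_fus):
        frac = simulate_post1R_fusion_null(n_ac, n_fus, 500, 2)
        assert 0.0 <= frac <= 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_post1R_fusion_null(2, 3, 10, 0)
        with pytest.raises(ValueError):
            simulate_post1R_fusion_null(2, 1, 0, 0)


class TestGenomeMap:
    def test_duplicate_ids_rejected(self):
        from paleokaryo.genome import Gene

        genes = [Gene("g1", "f1", "s", "c", 0), Gene("g1", "f2", "s", "c", 1)]
        with pytest.raises(ValueError):
            GenomeMap("s", {"c": genes})

    def test_indices_renumbered(self):
        from paleokaryo.genome import Gene

        genes = [Gene("g1", "f1", "s", "c", 5), Gene("g2", "f2", "s", "c", 9)]
        g = GenomeMap("s", {"c": genes})
        assert [x.index for x in g.genes_on("c")] == [0, 1]
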