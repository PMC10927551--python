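"""Tests for retention profiles, overlapping ratios and ohnolog calling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleokaryo.retention import (
    AnalysisThresholds,
    RetentionProfile,
    assign_orthologs,
    call_ohnologues,
    detect_fusions,
    multiplicity_per_ac,
    or_matrix,
    overlapping_ratio,
    retention_asymmetry,
    retention_profile,
    ward_cluster,
)
from paleokaryo.simulate import (
    ancestral_family_lists,
    apply_attrition,
    apply_wgd,
    make_ancestral_genome,
)


def prof(bits, ac="AC", sp="s", chrom="c"):
    return RetentionProfile(ac, sp, chrom, tuple(bits))


class TestRetentionProfile:
    def test_direct_lookup(self):
        fams = ["g1", "g2", "g3", "g4"]
        genes = ["h1", "h3"]
        fam_map = {"h1": "g1", "h3": "g3"}
        p = retention_profile(fams, genes, fam_map)
        assert p.vector == (1, 0, 1, 0)

    def test_empty_chromosome_all_zero(self):
        p = retention_profile(["g1", "g2"], [])
        assert p.vector == (0, 0) and p.n_retained == 0

    def test_binary_despite_multiplicity(self):
        p = retention_profile(
            ["g1", "g2"], ["h1", "h1b"], {"h1": "g1", "h1b": "g1"}
        )
        assert p.vector == (1, 0)

    def test_empty_ac_rejected(self):
        with pytest.raises(ValueError):
            retention_profile([], ["x"], {"x": "f"})

    def test_order_invariance(self):
        fams = [f"g{i}" for i in range(10)]
        genes = [f"h{i}" for i in range(6)]
        fam_map = {f"h{i}": f"g{2 * (i % 4)}" for i in range(6)}
        p1 = retention_profile(fams, genes, fam_map)
        p2 = retention_profile(fams, list(reversed(genes)), fam_map)
        assert p1.vector == p2.vector


class TestOverlappingRatio:
    def test_identity_and_disjoint(self):
        a = prof([1, 1, 0, 0])
        assert overlapping_ratio(a, a) == 1.0
        assert overlapping_ratio(a, prof([0, 0, 1, 1])) == 0.0

    def test_worked_example(self):
        a = prof([1, 1, 1, 0, 0])
        b = prof([1, 0, 1, 1, 1])
        assert overlapping_ratio(a, b) == pytest.approx(2 / 3)

    def test_zero_retention_undefined(self):
        with pytest.raises(ZeroDivisionError):
            overlapping_ratio(prof([1, 0]), prof([0, 0]))

    def test_mismatched_ac_rejected(self):
        with pytest.raises(ValueError):
            overlapping_ratio(prof([1], ac="A"), prof([1], ac="B"))

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                 min_size=1, max_size=40).filter(
            lambda v: any(a for a, _ in v) and any(b for _, b in v)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_range_and_symmetry(self, bits):
        a = prof([x for x, _ in bits])
        b = prof([y for _, y in bits])
        o = overlapping_ratio(a, b)
        assert 0.0 <= o <= 1.0
        assert o == overlapping_ratio(b, a)

    def test_insensitive_to_size_inflation(self):
        """Padding the larger chromosome with non-AC genes cannot change OR:
        the profile only sees AC families."""
        fams = [f"g{i}" for i in range(20)]
        fam_map = {f"h{i}": f"g{i}" for i in range(20)}
        fam_map.update({f"junk{i}": f"other{i}" for i in range(50)})
        small = [f"h{i}" for i in range(8)]
        big = [f"h{i}" for i in range(4, 20)]
        o1 = overlapping_ratio(
            retention_profile(fams, small, fam_map),
            retention_profile(fams, big, fam_map),
        )
        o2 = overlapping_ratio(
            retention_profile(fams, small, fam_map),
            retention_profile(fams, big + [f"junk{i}" for i in range(50)], fam_map),
        )
        assert o1 == o2


class TestORMatrix:
    def test_min_retained_filter(self):
        profiles = [
            prof([1] * 25 + [0] * 5, chrom="c1"),
            prof([0] * 11 + [1] * 19, chrom="c2"),  # 19 < 20: excluded
            prof([1] * 30, chrom="c3"),
        ]
        m = or_matrix(profiles, min_retained=20)
        assert m.values.shape == (2, 2)
        assert m.excluded == [("s", "c2")]

    def test_single_survivor_flagged_empty(self):
        m = or_matrix([prof([1] * 30)], min_retained=20)
        assert m.empty and m.values.shape == (1, 1)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        profiles = [
            prof(rng.integers(0, 2, 40), chrom=f"c{i}") for i in range(5)
        ]
        profiles = [p for p in profiles if p.n_retained > 0]
        m = or_matrix(profiles, min_retained=1)
        for i, j in itertools.combinations(range(len(m.chromosomes)), 2):
            pi = profiles[i]
            pj = profiles[j]
            assert m.values[i, j] == pytest.approx(overlapping_ratio(pi, pj))
            assert m.values[i, j] == m.values[j, i]


class TestOhnologCalling:
    @staticmethod
    def _matrix(values, n=30):
        k = len(values)
        profiles = []
        chroms = [(("s", f"c{i}")) for i in range(k)]
        import pandas as pd

        from paleokaryo.retention import ORMatrix

        return ORMatrix(
            "AC", chroms, np.array(values),
            {c: n for c in chroms},
        )

    def test_threshold_strictly_exceeded(self):
        m = self._matrix([[1.0, 0.10], [0.10, 1.0]])
        g, comps, _ = call_ohnologues(m, 0.15)
        assert g.number_of_edges() == 0
        m2 = self._matrix([[1.0, 0.15], [0.15, 1.0]])
        g2, _, _ = call_ohnologues(m2, 0.15)
        assert g2.number_of_edges() == 0  # exactly at threshold: no edge
        m3 = self._matrix([[1.0, 0.1501], [0.1501, 1.0]])
        g3, _, _ = call_ohnologues(m3, 0.15)
        assert g3.number_of_edges() == 1

    def test_triangle_is_one_set_in_both_views(self):
        m = self._matrix(
            [[1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0]]
        )
        _g, comps, cliques = call_ohnologues(m, 0.15)
        assert len(comps) == 1 and len(comps[0]) == 3
        assert len(cliques) == 1 and len(cliques[0]) == 3

    def test_multiplicity_counts(self):
        m = self._matrix([[1.0, 0.3], [0.3, 1.0]])
        calls = {"AC1": call_ohnologues(m, 0.15)}
        assert multiplicity_per_ac(calls) == {"AC1": 2}
        lone = self._matrix([[1.0, 0.05], [0.05, 1.0]])
        calls = {"AC2": call_ohnologues(lone, 0.15)}
        assert multiplicity_per_ac(calls) == {"AC2": 1}


class TestWardClustering:
    def test_two_items_single_merge(self):
        out = ward_cluster(np.array([[0.0, 0.4], [0.4, 0.0]]), labels=["a", "b"])
        assert len(out["merges"]) == 1
        assert out["merges"][0][2] == pytest.approx(0.4)

    def test_tight_pairs_merge_first(self):
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        out = ward_cluster(d, labels=["a", "b", "c", "d"])
        first_two = {tuple(sorted(m[:2])) for m in out["merges"][:2]}
        assert first_two == {(0, 1), (2, 3)}
        assert out["cut"](2) in (
            {"a": 0, "b": 0, "c": 1, "d": 1},
            {"a": 1, "b": 1, "c": 0, "d": 0},
        )

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0]]), labels=["a"])

    def test_matches_brute_force_lance_williams(self):
        """Merge heights equal an independent full-recompute LW oracle."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = 6
            raw = rng.random((n, n))
            d0 = (raw + raw.T) / 2
            np.fill_diagonal(d0, 0.0)
            labels = [f"l{i}" for i in range(n)]
            out = ward_cluster(d0.copy(), labels=labels)
            # oracle: clusters as frozensets, distances in a dict, full scan
            dist = {
                frozenset([frozenset([i]), frozenset([j])]): d0[i, j]
                for i in range(n)
                for j in range(i + 1, n)
            }
            sizes = {frozenset([i]): 1 for i in range(n)}
            alive = set(sizes)
            heights = []
            while len(alive) > 1:
                pair = min(
                    (
                        (dist[frozenset([a, b])], sorted(min(a) for a in (a, b)))
                        + ((a, b),)
                        for a in alive
                        for b in alive
                        if a != b
                    ),
                    key=lambda t: (t[0], t[1]),
                )
                h, _tie, (a, b) = pair
                heights.append(h)
                ab = a | b
                for c in alive - {a, b}:
                    na, nb, nc = sizes[a], sizes[b], sizes[c]
                    tot = na + nb + nc
                    dist[frozenset([ab, c])] = (
                        (na + nc) / tot * dist[frozenset([a, c])]
                        + (nb + nc) / tot * dist[frozenset([b, c])]
                        - nc / tot * h
                    )
                alive -= {a, b}
                alive.add(ab)
                sizes[ab] = sizes[a] + sizes[b]
            assert np.allclose([m[2] for m in out["merges"]], heights)

    def test_orthologous_chromosomes_pair_in_dendrogram(self):
        """With rediploidization loss but no post-split attrition, each
        orthologous chromosome pair forms a two-leaf clade."""
        from paleokaryo.retention import RetentionProfile
        from paleokaryo.simulate import EvolutionScenario, run_scenario

        scn = EvolutionScenario(
            1, 150,
            [
                {"type": "wgd", "multiplicity": 2},
                {"type": "attrition", "loss_rate": 0.3},
                {"type": "speciate", "names": ["sp1", "sp2"], "loss_rate": 0.0},
            ],
            seed=21,
        )
        res = run_scenario(scn)
        fams = ancestral_family_lists(1, 150)["AC01"]
        profiles = []
        for sp in ("sp1", "sp2"):
            for chrom in sorted(res.genomes[sp].chromosomes):
                profiles.append(
                    retention_profile(
                        fams, res.genomes[sp].genes_on(chrom), ac_id="AC01",
                        species=sp, chrom_name=chrom,
                    )
                )
        m = or_matrix(profiles, min_retained=10)
        out = ward_cluster(m)
        clusters = out["cut"](2)
        by_chrom = {}
        for label, cl in clusters.items():
            by_chrom.setdefault(label.split(":")[1], set()).add(cl)
        # the two species' copies of the same chromosome always co-cluster
        assert all(len(v) == 1 for v in by_chrom.values())
        assert len({tuple(v)[0] for v in by_chrom.values()}) == 2


class TestAssignOrthologs:
    @staticmethod
    def _frame(values, rows, cols):
        import pandas as pd

        return pd.DataFrame(values, index=rows, columns=cols)

    def test_mutual_best_one_to_one(self):
        inter = self._frame([[0.84, 0.1], [0.1, 0.8]], ["a1", "a2"], ["b1", "b2"])
        out = assign_orthologs(inter, 0.15)
        rows = {r.chromosome: r.klass for r in out.itertuples(index=False)}
        assert rows["a1"] == "1:1" and rows["a2"] == "1:1"

    def test_close_partners_ambiguous(self):
        inter = self._frame([[0.60, 0.58]], ["a1"], ["b1", "b2"])
        out = assign_orthologs(inter, 0.15)
        row = out[out["chromosome"] == "a1"].iloc[0]
        assert row["klass"] == "1:2"
        assert row["partner"] == "b1;b2"

    def test_below_threshold_unassigned(self):
        inter = self._frame([[0.10, 0.05]], ["a1"], ["b1", "b2"])
        out = assign_orthologs(inter, 0.15)
        assert set(out["klass"]) == {"unassigned"}


class TestRetentionAsymmetry:
    def test_ratios(self):
        out = retention_asymmetry([(25, 25), (50, 114)])
        assert out["ratios"][0] == pytest.approx(1.0)
        assert out["ratios"][1] == pytest.approx(2.28)

    def test_identical_groups_null(self):
        pairs = [(10, 20)] * 8 + [(10, 20)] * 8
        groups = ["g1"] * 8 + ["g2"] * 8
        out = retention_asymmetry(pairs, groups)
        assert out["ranksum_p"] == pytest.approx(1.0)
        assert out["group_medians"]["g1"] == out["group_medians"]["g2"]

    def test_zero_counts_excluded(self):
        out = retention_asymmetry([(0, 10), (5, 10)])
        assert out["ratios"] == [2.0]


class TestDetectFusions:
    def test_single_ac_contributes_zero(self):
        total, detail = detect_fusions({"c1": {"AC1": 100}})
        assert total == 0

    def test_two_acs_contribute_one(self):
        total, _ = detect_fusions({"c1": {"AC1": 40, "AC2": 35}})
        assert total == 1

    def test_min_frag_threshold(self):
        total, _ = detect_fusions({"c1": {"AC1": 40, "AC2": 9}}, min_frag=10)
        assert total == 0

    def test_truth_round_trip_triple_fusion(self):
        """A simulated fusion of three AC descendants contributes 2 events."""
        from paleokaryo.simulate import apply_fusion, descent_of

        g = make_ancestral_genome(4, 50, 0)
        g = apply_fusion(g, "AC01", "AC02")
        g = apply_fusion(g, "AC01+AC02", "AC03")
        comp = {}
        for chrom in g.chromosomes:
            counts = {}
            for gene in g.genes_on(chrom):
                ac = gene.family_id.split("g")[0]
                counts[ac] = counts.get(ac, 0) + 1
            comp[chrom] = counts
        total, detail = detect_fusions(comp)
        assert total == 2
        row = detail[detail["chromosome"] == "AC01+AC02+AC03"].iloc[0]
        assert row["n_acs"] == 3


class TestMonotoneDegradation:
    def test_mean_or_decreases_with_loss(self):
        """Heavier independent per-copy loss yields lower expected OR."""
        means = []
        for loss in (0.1, 0.3, 0.5):
            fams = ancestral_family_lists(200, 100)
            g = make_ancestral_genome(200, 100)
            g = apply_wgd(g, 2, "auto")
            g = apply_attrition(g, loss_rate=loss, seed=31)
            ors = []
            for ac in fams:
                p = [
                    retention_profile(fams[ac], g.genes_on(f"{ac}~{c}"), ac_id=ac)
                    for c in "ab"
                ]
                if min(x.n_retained for x in p) > 0:
                    ors.append(overlapping_ratio(p[0], p[1]))
            means.append(np.mean(ors))
        assert means[0] > means[1] > means[2]


class TestThresholds:
    def test_defaults_match_study_constants(self):
        t = AnalysisThresholds()
        assert (t.or_ohnolog_min, t.min_retained) == (0.15, 20)
        assert (t.q_max, t.rbh_evalue_max) == (0.05, 1e-6)
        assert (t.anchor_min_multi, t.tpm_min, t.strong_spec_frac) == (5, 5.0, 0.40)

    def test_validation(self):
        with pytest.raises(ValueError):
            AnalysisThresholds(or_ohnolog_min=1.5)
        with pytest.raises(ValueError):
            AnalysisThresholds(min_retained=0)
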