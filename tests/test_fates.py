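"""Tests for expression-fate classification and ACR context annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paleokaryo.fates import (
    acr_counts_per_gene,
    classify_acr_context,
    classify_fate,
    classify_pairs,
    expression_domains,
    quantile_normalize,
    specialization_tissue_profile,
    tss_distance_cdf,
)
from paleokaryo.simulate import (
    simulate_expression,
    simulate_regulatory_landscape,
)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"t1": [1.0, 5.0, 2.0], "t2": [1.0, 5.0, 2.0]})
        out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_permuted_columns_share_sorted_values(self):
        m = pd.DataFrame({"t1": [3.0, 1.0, 7.0], "t2": [7.0, 3.0, 1.0]})
        out = quantile_normalize(m)
        assert np.allclose(np.sort(out["t1"]), np.sort(out["t2"]))

    def test_hand_computed_reference(self):
        # columns sorted: [1,4,6] and [2,3,9] -> reference [1.5, 3.5, 7.5]
        m = pd.DataFrame({"t1": [4.0, 1.0, 6.0], "t2": [2.0, 9.0, 3.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["t1"], [3.5, 1.5, 7.5])
        assert np.allclose(out["t2"], [1.5, 7.5, 3.5])

    def test_ties_get_averaged_reference(self):
        m = pd.DataFrame({"t1": [1.0, 1.0, 5.0], "t2": [2.0, 4.0, 9.0]})
        out = quantile_normalize(m)
        # reference [1.5, 2.5, 7.0]; the tied pair spans ranks 1-2
        assert np.allclose(out["t1"].iloc[:2], [2.0, 2.0])

    def test_single_column_warns_identity(self):
        m = pd.DataFrame({"t1": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)


class TestExpressionDomains:
    def test_strict_threshold(self):
        m = pd.DataFrame(
            {"brain": [5.1, 5.0], "liver": [0.0, 12.0]},
            index=["g1", "g2"],
        )
        d = expression_domains(m, 5.0)
        assert d["g1"] == {"brain"}
        assert d["g2"] == {"liver"}  # exactly 5.0 is "not expressed"

    def test_silent_gene_empty_set(self):
        m = pd.DataFrame({"brain": [0.0], "liver": [0.0]}, index=["g"])
        assert expression_domains(m, 5.0)["g"] == set()


class TestClassifyFate:
    def test_redundancy(self):
        c = classify_fate({"brain", "liver"}, {"brain", "liver"})
        assert c.fate == "redundancy" and c.spec_grade == "n/a"

    def test_subfunctionalization(self):
        c = classify_fate({"brain", "heart"}, {"liver", "heart"})
        assert c.fate == "subfunctionalization"

    def test_specialization_strong(self):
        c = classify_fate({"brain"}, {"brain", "liver", "heart"})
        assert (c.fate, c.spec_grade) == ("specialization", "strong")  # 1/3 < 0.40

    def test_specialization_mild_at_boundary(self):
        # 2/5 = 0.40 is not < 0.40 -> mild
        c = classify_fate({"a", "b"}, {"a", "b", "c", "d", "e"})
        assert (c.fate, c.spec_grade) == ("specialization", "mild")

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            classify_fate(set(), {"brain"})

    def test_exhaustive_partition_four_tissues(self):
        """Every non-empty domain-set pair receives exactly one fate."""
        universe = ["t1", "t2", "t3", "t4"]
        subsets = [
            set(c)
            for r in range(1, 5)
            for c in itertools.combinations(universe, r)
        ]
        for a in subsets:
            for b in subsets:
                c = classify_fate(a, b)
                checks = [
                    c.fate == "redundancy" and a == b,
                    c.fate == "subfunctionalization"
                    and bool(a - b) and bool(b - a),
                    c.fate == "specialization" and (a < b or b < a),
                ]
                assert sum(checks) == 1
                if c.fate == "specialization":
                    narrow, broad = (a, b) if a < b else (b, a)
                    assert (c.spec_grade == "strong") == (
                        len(narrow) / len(broad) < 0.40
                    )


class TestSimulatedExpressionRoundTrip:
    TISSUES = ["brain", "gill", "heart", "gut", "liver", "muscle", "skin",
               "gonad", "kidney"]

    def _recover(self, matrix, truth):
        calls, excluded = classify_pairs(
            matrix, truth[["pair_id", "gene_a", "gene_b"]]
        )
        assert excluded.empty
        got = {c.pair_id: (c.fate, c.spec_grade) for c in calls}
        hits = 0
        for row in truth.itertuples(index=False):
            fate, grade = got[row.pair_id]
            if row.fate == "redundancy":
                hits += fate == "redundancy"
            elif row.fate == "subfunctionalization":
                hits += fate == "subfunctionalization"
            elif row.fate == "strong_spec":
                hits += (fate, grade) == ("specialization", "strong")
            else:
                hits += (fate, grade) == ("specialization", "mild")
        return hits / len(truth)

    def test_pure_redundancy_recovered(self):
        matrix, truth = simulate_expression(
            50, {"redundancy": 1.0}, self.TISSUES, seed=0
        )
        assert self._recover(matrix, truth) == 1.0

    def test_mixed_fates_zero_noise_recovered(self):
        matrix, truth = simulate_expression(
            200,
            {"redundancy": 0.25, "subfunctionalization": 0.25,
             "strong_spec": 0.25, "mild_spec": 0.25},
            self.TISSUES, seed=1,
        )
        assert self._recover(matrix, truth) == 1.0

    def test_bounded_noise_keeps_recovery(self):
        matrix, truth = simulate_expression(
            300,
            {"redundancy": 0.25, "subfunctionalization": 0.25,
             "strong_spec": 0.25, "mild_spec": 0.25},
            self.TISSUES, noise_sd=0.3, seed=2,
        )
        assert self._recover(matrix, truth) >= 0.99

    def test_strong_spec_domain_sizes_respect_40_percent(self):
        matrix, truth = simulate_expression(
            100, {"strong_spec": 1.0}, self.TISSUES, seed=3
        )
        for row in truth.itertuples(index=False):
            na = len(row.domains_a.split(";"))
            nb = len(row.domains_b.split(";"))
            assert min(na, nb) / max(na, nb) < 0.40

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_expression(10, {"redundancy": 1.0}, ["one"], seed=0)
        with pytest.raises(ValueError):
            simulate_expression(
                10, {"redundancy": 0.5}, ["a", "b"], seed=0
            )  # proportions must sum to 1
        with pytest.raises(ValueError):
            simulate_expression(
                10, {"redundancy": 1.0}, ["a", "b"], tpm_lo=6.0, seed=0
            )  # low state above the threshold


class TestSpecializationProfile:
    def test_counts_narrow_copy_tissues(self):
        calls = [
            classify_fate({"brain"}, {"brain", "liver", "gut"}, pair_id="p1"),
            classify_fate({"brain", "gut"}, {"brain", "liver", "gut", "skin",
                                             "heart", "gonad"}, pair_id="p2"),
            classify_fate({"liver"}, {"liver", "gut"}, pair_id="p3"),  # mild
        ]
        prof = specialization_tissue_profile(calls)
        assert prof["brain"] == 2
        assert prof["gut"] == 1
        assert "liver" not in prof.index

    def test_no_strong_calls_empty(self):
        calls = [classify_fate({"a"}, {"a"}, pair_id="p")]
        assert specialization_tissue_profile(calls).empty


def _gene_models():
    # one + strand gene with TSS 10_000 and one - strand gene with TSS 99_999
    return pd.DataFrame(
        [
            ("gp", "chr1", 10_000, 20_000, "+", "gene"),
            ("gp", "chr1", 10_000, 11_000, "+", "exon"),
            ("gp", "chr1", 16_000, 17_000, "+", "exon"),
            ("gm", "chr1", 90_000, 100_000, "-", "gene"),
            ("gm", "chr1", 99_000, 100_000, "-", "exon"),
            ("gm", "chr1", 93_000, 94_000, "-", "exon"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "feature"],
    )


class TestACRContext:
    def _one(self, start, end):
        acr = pd.DataFrame(
            [("chr1", start, end, "a1")], columns=["chrom", "start", "end", "name"]
        )
        (ann,) = classify_acr_context(acr, _gene_models())
        return ann

    def test_promoter_upstream_plus_strand(self):
        ann = self._one(9_400, 9_600)  # TSS-500
        assert ann.category == "promoter" and ann.gene == "gp"
        assert ann.tss_distance < 0  # upstream

    def test_promoter_windows_strand_aware(self):
        # 500 bp downstream of the minus-strand TSS is at lower coordinates
        ann = self._one(99_400, 99_600)
        assert ann.category == "promoter" and ann.gene == "gm"
        assert ann.tss_distance > 0  # downstream in gene orientation

    def test_proximal_at_minus_3000(self):
        ann = self._one(6_900, 7_100)
        assert ann.category == "proximal"

    def test_exonic_outside_proximal(self):
        ann = self._one(16_400, 16_600)  # inside the TSS+6k exon
        assert ann.category == "exonic"

    def test_distal_far_from_everything(self):
        ann = self._one(50_000, 50_200)
        assert ann.category == "distal"

    def test_one_base_overlap_suffices(self):
        # promoter window of gp covers [9000, 10500]; ACR ending at 9001
        # overlaps it by exactly one base
        ann = self._one(8_801, 9_001)
        assert ann.category == "promoter"
        assert self._one(8_800, 9_000).category == "proximal"

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            self._one(5_000, 5_000)


class TestACRRoundTrip:
    def test_planted_categories_recovered(self):
        acrs, genes = simulate_regulatory_landscape(
            200, acr_rate_per_gene=3.0, distal_fraction=0.25, seed=4
        )
        annots = classify_acr_context(acrs, genes)
        agree = np.mean(
            [a.category == t for a, t in zip(annots, acrs["truth_category"])]
        )
        assert agree >= 0.99

    def test_distal_fraction_zero(self):
        acrs, _ = simulate_regulatory_landscape(
            50, acr_rate_per_gene=2.0, distal_fraction=0.0, seed=5
        )
        assert (acrs["truth_category"] != "distal").all()

    def test_categories_partition_totals(self):
        acrs, genes = simulate_regulatory_landscape(100, 3.0, 0.3, seed=6)
        annots = classify_acr_context(acrs, genes)
        counts = pd.Series([a.category for a in annots]).value_counts()
        assert counts.sum() == len(acrs)
        assert set(counts.index) <= {"promoter", "proximal", "exonic", "distal"}


class TestACRCountsAndCDF:
    def test_counts_conserve_assignments(self):
        acrs, genes = simulate_regulatory_landscape(80, 2.0, 0.2, seed=7)
        annots = classify_acr_context(acrs, genes)
        all_genes = sorted(genes[genes["feature"] == "gene"]["gene_id"])
        counts, _tests = acr_counts_per_gene(annots, all_genes=all_genes)
        assert counts.sum() == len(annots)
        assert (counts.index == all_genes).all()

    def test_ranksum_tests_bonferroni(self):
        acrs, genes = simulate_regulatory_landscape(120, 2.0, 0.2, seed=8)
        annots = classify_acr_context(acrs, genes)
        gene_ids = sorted(genes[genes["feature"] == "gene"]["gene_id"])
        classes = {
            g: ("devel" if i % 3 == 0 else "non-devel")
            for i, g in enumerate(gene_ids)
        }
        counts, tests = acr_counts_per_gene(annots, gene_ids, classes)
        assert len(tests) == 1
        assert (tests["p_bonferroni"] >= tests["p"]).all()

    def test_cdf_shape(self):
        from paleokaryo.fates import ACRAnnotation

        annots = [
            ACRAnnotation("c", 0, 10, "a", "distal", "g", 1_000),
            ACRAnnotation("c", 0, 10, "b", "distal", "g", -10_000),
        ]
        cdf = tss_distance_cdf(annots)
        assert list(cdf["cumulative"]) == [0.5, 1.0]
        assert list(cdf["distance"]) == [1_000.0, 10_000.0]
        scaled = tss_distance_cdf(annots, scale_by=1_000.0)
        assert list(scaled["distance"]) == [1.0, 10.0]
        assert (np.diff(cdf["cumulative"]) >= 0).all()
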