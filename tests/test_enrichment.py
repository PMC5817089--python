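import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualmeth.enrichment import (
    chisq_overlap,
    expand_annotations,
    neuronal_term_enrichment,
    permutation_enrichment,
    permutation_enrichment_vs_set,
)
from tests.conftest import make_annotation


def five_locus_annotation():
    return make_annotation(
        [
            ("p0", "chr1", 10, (("g", "Body"),), "OpenSea"),
            ("p1", "chr1", 20, (("g", "Body"),), "OpenSea"),
            ("p2", "chr1", 30, (("g", "TSS200"),), "Island"),
            ("p3", "chr1", 40, (("g", "TSS200"),), "Island"),
            ("p4", "chr1", 50, (("g", "TSS200"),), "Island"),
        ]
    )


class TestExpandAnnotations:
    def test_multi_group_locus_two_occurrences(self):
        ann = make_annotation(
            [("p", "chr1", 1, (("g1", "Body"), ("g2", "TSS200")), "OpenSea")]
        )
        counts = expand_annotations(["p"], ann)
        assert counts == Counter({"Body": 1, "TSS200": 1})

    def test_intergenic_contributes_intergenic(self):
        ann = make_annotation([("p", "chr1", 1, (), "OpenSea")])
        assert expand_annotations(["p"], ann) == Counter({"intergenic": 1})

    def test_multiset_size_conserved(self):
        ann = five_locus_annotation()
        counts = expand_annotations(list(ann.index), ann)
        assert sum(counts.values()) == 5

    def test_island_expansion(self):
        ann = five_locus_annotation()
        counts = expand_annotations(["p0", "p2"], ann, kind="island")
        assert counts == Counter({"OpenSea": 1, "Island": 1})


class TestPermutationEnrichment:
    def test_matches_exact_hypergeometric(self):
        # drawing 2 of 5 loci: P(both Body) = C(2,2)/C(5,2) = 0.1
        ann = five_locus_annotation()
        res = permutation_enrichment(
            ["p0", "p1"], list(ann.index), ann, n_perm=100_000, seed=1
        )
        p_exact = 0.1
        se = np.sqrt(p_exact * (1 - p_exact) / 100_000)
        assert abs(res.loc["Body", "p_over"] - p_exact) < 3 * se

    def test_exact_enumeration_all_draws(self):
        # p_over/p_under converge to full-enumeration tail probabilities
        rng = np.random.default_rng(3)
        ann = make_annotation(
            [
                (f"p{i}", "chr1", 10 * (i + 1),
                 ((("g", "Body"),) if rng.random() < 0.5 else (("g", "TSS200"),)),
                 "OpenSea")
                for i in range(9)
            ]
        )
        universe = list(ann.index)
        observed = ["p0", "p1", "p2"]
        n_perm = 40_000
        res = permutation_enrichment(observed, universe, ann, n_perm=n_perm, seed=4)
        actual = expand_annotations(observed, ann)
        body = np.array(
            [1 if ann.loc[p, "gene_entries"][0][1] == "Body" else 0 for p in universe]
        )
        counts = [
            body[list(combo)].sum()
            for combo in itertools.combinations(range(9), 3)
        ]
        counts = np.array(counts)
        exact_over = (counts >= actual["Body"]).mean()
        se = np.sqrt(exact_over * (1 - exact_over) / n_perm) + 1e-9
        assert abs(res.loc["Body", "p_over"] - exact_over) < 3 * se + 1 / n_perm

    def test_observed_equals_universe_degenerate(self):
        ann = five_locus_annotation()
        res = permutation_enrichment(
            list(ann.index), list(ann.index), ann, n_perm=2000, seed=0
        )
        assert (res.loc[res["actual"] > 0, "p_over"] == 1.0).all()
        assert (res.loc[res["actual"] > 0, "p_under"] == 1.0).all()

    def test_seeded_reproducibility(self):
        ann = five_locus_annotation()
        a = permutation_enrichment(["p0"], list(ann.index), ann, n_perm=5000, seed=9)
        b = permutation_enrichment(["p0"], list(ann.index), ann, n_perm=5000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_outside_universe_rejected(self):
        ann = five_locus_annotation()
        with pytest.raises(ValueError, match="subset"):
            permutation_enrichment(["p0"], ["p1", "p2"], ann, n_perm=1000)

    def test_tail_p_values_overlap_at_least_one(self):
        ann = five_locus_annotation()
        res = permutation_enrichment(
            ["p0", "p2"], list(ann.index), ann, n_perm=5000, seed=2
        )
        assert ((res["p_over"] + res["p_under"]) >= 1.0).all()

    def test_legacy_p_can_reach_zero(self):
        ann = five_locus_annotation()
        res = permutation_enrichment(
            ["p0", "p1"], list(ann.index), ann, n_perm=500, seed=0,
            legacy_p=True, strict_tie=True,
        )
        assert (res["p_under"] >= 0).all()
        add_one = permutation_enrichment(
            ["p0", "p1"], list(ann.index), ann, n_perm=500, seed=0
        )
        assert (add_one["p_over"] > 0).all()

    def test_calibration_super_uniform(self):
        # observed sets drawn uniformly from the universe give honest p_over
        rng = np.random.default_rng(7)
        ann = make_annotation(
            [
                (f"p{i}", "chr1", 10 * (i + 1),
                 ((("g", "Body"),) if i < 30 else (("g", "TSS200"),)), "OpenSea")
                for i in range(60)
            ]
        )
        universe = list(ann.index)
        pvals = []
        for rep in range(200):
            observed = list(rng.choice(universe, size=8, replace=False))
            res = permutation_enrichment(observed, universe, ann, n_perm=500, seed=rep)
            pvals.append(res.loc["Body", "p_over"])
        pvals = np.array(pvals)
        for t in (0.1, 0.25, 0.5):
            assert (pvals <= t).mean() <= t + 0.08


class TestAlternateUniverse:
    def test_full_universe_reduces_to_standard(self):
        ann = five_locus_annotation()
        a = permutation_enrichment(
            ["p0", "p1"], list(ann.index), ann, n_perm=3000, seed=5
        )
        b = permutation_enrichment_vs_set(
            ["p0", "p1"], list(ann.index), ann, n_perm=3000, seed=5
        )
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_draw_gives_minimal_p(self):
        ann = make_annotation(
            [("a", "chr1", 1, (("g", "Body"),), "OpenSea")]
            + [(f"b{i}", "chr1", 10 + i, (("g", "TSS200"),), "OpenSea") for i in range(4)]
        )
        n_perm = 2000
        res = permutation_enrichment_vs_set(
            ["a"], [f"b{i}" for i in range(4)], ann, n_perm=n_perm, seed=0
        )
        assert res.loc["Body", "p_over"] == pytest.approx(1 / (n_perm + 1))

    def test_oversized_observed_rejected(self):
        ann = five_locus_annotation()
        with pytest.raises(ValueError, match="larger"):
            permutation_enrichment_vs_set(
                ["p0", "p1", "p2"], ["p3", "p4"], ann, n_perm=1000
            )


class TestChisqOverlap:
    def test_symmetric_table_is_null(self):
        t = chisq_overlap(
            set(range(20)), set(range(10)) | set(range(20, 30)), set(range(40))
        )
        assert (t.a, t.b, t.c, t.d) == (10, 10, 10, 10)
        assert t.chi2 == 0.0
        assert t.p == 1.0

    def test_worked_example(self):
        # a=30, b=10, c=10, d=30 -> chi2 = 18.05
        t = chisq_overlap(
            set(range(40)), set(range(30)) | set(range(40, 50)), set(range(80))
        )
        assert (t.a, t.b, t.c, t.d) == (30, 10, 10, 30)
        assert t.chi2 == pytest.approx(18.05, abs=1e-9)
        assert t.p == pytest.approx(2.15e-5, rel=0.01)

    def test_swap_symmetry(self):
        s1 = set(range(25))
        s2 = set(range(15, 50))
        uni = set(range(100))
        assert chisq_overlap(s1, s2, uni).chi2 == chisq_overlap(s2, s1, uni).chi2

    def test_matches_independent_implementation_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 60, size=4)
            universe = set(range(a + b + c + d))
            ids = list(universe)
            s1 = set(ids[: a + b])
            s2 = set(ids[:a]) | set(ids[a + b : a + b + c])
            t = chisq_overlap(s1, s2, universe)
            n = a + b + c + d
            num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
            den = (a + b) * (c + d) * (a + c) * (b + d)
            assert t.chi2 == pytest.approx(num / den, abs=1e-9)

    def test_agrees_with_scipy_continuity_correction(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(5, 80, size=4)
            ids = list(range(a + b + c + d))
            s1, s2 = set(ids[: a + b]), set(ids[:a]) | set(ids[a + b : a + b + c])
            t = chisq_overlap(s1, s2, set(ids))
            res = stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True)
            assert t.chi2 == pytest.approx(res.statistic, abs=1e-9)
            assert t.p == pytest.approx(res.pvalue, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_overlap(set(), {1}, {1, 2})


class TestNeuronalTermEnrichment:
    def test_disjoint_reference_no_association(self):
        obs = {f"t{i}" for i in range(10)}
        uni = {f"t{i}" for i in range(40)}
        ref = {f"t{i}" for i in range(20, 35)}
        t = neuronal_term_enrichment(obs, uni, ref)
        assert t.a == 0

    def test_observed_inside_reference_positive_association(self):
        uni = {f"t{i}" for i in range(60)}
        ref = {f"t{i}" for i in range(25)}
        obs = {f"t{i}" for i in range(12)}
        t = neuronal_term_enrichment(obs, uni, ref)
        assert t.chi2 > 0
        assert t.a * t.d > t.b * t.c  # positive direction

    def test_delegates_to_chisq_overlap(self):
        uni = {f"t{i}" for i in range(50)}
        ref = {f"t{i}" for i in range(20)}
        obs = {f"t{i}" for i in range(5, 30)}
        direct = chisq_overlap(obs, ref & uni, uni)
        via = neuronal_term_enrichment(obs, uni, ref)
        assert via == direct
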