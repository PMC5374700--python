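import math

import numpy as np
import pandas as pd
import pytest

from netmdc.datatypes import AnnotationTable, GeneSetCollection
from netmdc.enrichment import (
    hypergeom_upper_tail,
    hypergeometric_enrichment,
    internal_similarity,
    permutation_group_significance,
    perturbational_overlap,
)
from netmdc.synthetic import SimulationDesign, CompoundDesign, generate_annotations


def exact_tail(overlap, universe, module_size, set_size):
    """Independent oracle: exact combinatorial tail sum."""
    total = 0.0
    for k in range(overlap, min(module_size, set_size) + 1):
        total += (
            math.comb(set_size, k)
            * math.comb(universe - set_size, module_size - k)
            / math.comb(universe, module_size)
        )
    return total


class TestHypergeometric:
    @pytest.mark.parametrize(
        "overlap,universe,module,set_size",
        [(5, 100, 10, 10), (0, 50, 5, 5), (3, 200, 20, 15), (10, 100, 10, 10)],
    )
    def test_matches_exact_enumeration(self, overlap, universe, module, set_size):
        assert hypergeom_upper_tail(overlap, universe, module, set_size) == pytest.approx(
            exact_tail(overlap, universe, module, set_size), rel=1e-10
        )

    def test_module_equal_to_its_set_is_top_hit(self):
        universe = [f"g{i}" for i in range(500)]
        sets = GeneSetCollection({
            "target": frozenset(universe[:15]),
            "other1": frozenset(universe[100:130]),
            "other2": frozenset(universe[200:250]),
        })
        res = hypergeometric_enrichment(universe[:15], sets, universe, fdr_max=1.0)
        assert res[0].set_name == "target"
        assert res[0].fdr_q <= 0.25

    def test_zero_overlap_has_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        sets = GeneSetCollection({"s": frozenset(universe[50:60])})
        res = hypergeometric_enrichment(universe[:10], sets, universe, fdr_max=1.0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_disjoint_module_rejected(self):
        sets = GeneSetCollection({"s": frozenset({"g1"})})
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"zz"}, sets, {"g1", "g2"})

    def test_single_test_q_equals_p(self):
        universe = [f"g{i}" for i in range(100)]
        res = perturbational_overlap(universe[:10], universe[5:20], universe)
        assert res.fdr_q == res.p_value

    def test_calibration_valid_under_random_overlap(self):
        # the overlap statistic is discrete, so the null p-value is
        # super-uniform: P(p <= a) <= a at every level (test validity)
        rng = np.random.default_rng(0)
        universe = np.array([f"g{i}" for i in range(200)])
        ps = np.array([
            perturbational_overlap(
                rng.choice(universe, 20, replace=False),
                rng.choice(universe, 30, replace=False),
                universe,
            ).p_value
            for _ in range(1000)
        ])
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            rate = (ps <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / ps.size)
            assert rate <= alpha + 3 * se, alpha


def _toy_annotations():
    rows = []
    sets = {
        "c1": {"A", "B", "C", "D"},
        "c2": {"A", "B", "C", "E"},
        "c3": {"A", "B", "F", "G"},
    }
    for c, items in sets.items():
        for it in items:
            rows.append({"compound": c, "item": it})
    # pad the universe with unrelated compounds
    rng = np.random.default_rng(0)
    universe = [f"p{i}" for i in range(40)]
    for i in range(10):
        for it in rng.choice(universe, 4, replace=False):
            rows.append({"compound": f"x{i}", "item": it})
    return AnnotationTable(pd.DataFrame(rows))


class TestInternalSimilarity:
    def test_identical_item_sets_give_low_p(self):
        rows = [{"compound": c, "item": it}
                for c in ("a", "b", "c") for it in ("p1", "p2", "p3")]
        extra = [{"compound": "bg", "item": f"q{i}"} for i in range(30)]
        ann = AnnotationTable(pd.DataFrame(rows + extra))
        assert internal_similarity(["a", "b", "c"], ann) < 0.01

    def test_disjoint_item_sets_give_p_near_one(self):
        rows = [{"compound": "a", "item": "p1"}, {"compound": "b", "item": "p2"},
                {"compound": "c", "item": "p3"}]
        extra = [{"compound": "bg", "item": f"q{i}"} for i in range(30)]
        ann = AnnotationTable(pd.DataFrame(rows + extra))
        assert internal_similarity(["a", "b", "c"], ann) > 0.5

    def test_median_of_three_pairwise_fisher_pvalues(self):
        ann = _toy_annotations()
        universe = ann.items
        pairs = [("c1", "c2"), ("c1", "c3"), ("c2", "c3")]
        expected = np.median([
            exact_tail(
                len(ann.items_for(a) & ann.items_for(b)),
                len(universe),
                len(ann.items_for(a)),
                len(ann.items_for(b)),
            )
            for a, b in pairs
        ])
        assert internal_similarity(["c1", "c2", "c3"], ann) == pytest.approx(expected)

    def test_fewer_than_two_annotated_compounds_gives_nan(self):
        ann = _toy_annotations()
        assert math.isnan(internal_similarity(["c1", "unknown"], ann))


class TestPermutationSignificance:
    def test_best_possible_score_flagged(self):
        ann = _toy_annotations()
        res = permutation_group_significance(3, ann, observed=0.0, n_perm=200, seed=1)
        assert res.permutation_p == pytest.approx(1 / 201)
        assert res.best_possible

    def test_median_permutation_score_gives_p_about_half(self):
        # dense annotations so pairwise overlaps (hence scores) vary
        rng = np.random.default_rng(5)
        universe = [f"p{i}" for i in range(30)]
        rows = [
            {"compound": f"c{i}", "item": it}
            for i in range(16)
            for it in rng.choice(universe, rng.integers(8, 15), replace=False)
        ]
        ann = AnnotationTable(pd.DataFrame(rows))
        compounds = np.array(ann.compounds)
        scores = []
        for _ in range(400):
            sel = rng.choice(compounds, 3, replace=False)
            scores.append(internal_similarity(sel, ann))
        observed = float(np.median(scores))
        res = permutation_group_significance(3, ann, observed, n_perm=400, seed=2)
        assert res.permutation_p == pytest.approx(0.5, abs=0.15)

    def test_reproducible_under_fixed_seed(self):
        ann = _toy_annotations()
        r1 = permutation_group_significance(3, ann, 0.3, n_perm=100, seed=9)
        r2 = permutation_group_significance(3, ann, 0.3, n_perm=100, seed=9)
        assert r1.permutation_p == r2.permutation_p

    def test_oversized_group_rejected(self):
        ann = _toy_annotations()
        with pytest.raises(ValueError):
            permutation_group_significance(1000, ann, 0.5, n_perm=100)


class TestSyntheticAnnotations:
    def test_full_sharing_gives_significant_similarity(self):
        design = SimulationDesign(
            n_genes=50, module_sizes=[20], control_rho=[0.5], n_control_samples=10,
            compounds=[CompoundDesign(f"c{i}", "G1", 5) for i in range(4)]
            + [CompoundDesign(f"d{i}", f"B{i}", 5) for i in range(12)],
            seed=0,
        )
        ann = generate_annotations(design, sharing=1.0, seed=3)
        obs = internal_similarity([f"c{i}" for i in range(4)], ann)
        res = permutation_group_significance(4, ann, obs, n_perm=200, seed=4)
        assert res.permutation_p < 0.05

    def test_no_sharing_not_significant(self):
        design = SimulationDesign(
            n_genes=50, module_sizes=[20], control_rho=[0.5], n_control_samples=10,
            compounds=[CompoundDesign(f"c{i}", "G1", 5) for i in range(4)]
            + [CompoundDesign(f"d{i}", f"B{i}", 5) for i in range(12)],
            seed=0,
        )
        ann = generate_annotations(design, sharing=0.0, seed=5)
        obs = internal_similarity([f"c{i}" for i in range(4)], ann)
        res = permutation_group_significance(4, ann, obs, n_perm=200, seed=6)
        assert res.permutation_p > 0.05

    def test_deterministic_under_fixed_seed(self):
        design = SimulationDesign(
            n_genes=50, module_sizes=[20], control_rho=[0.5], n_control_samples=10,
            compounds=[CompoundDesign("c1", "G1", 5), CompoundDesign("c2", "G1", 5)],
            seed=0,
        )
        a1 = generate_annotations(design, sharing=0.5, seed=7)
        a2 = generate_annotations(design, sharing=0.5, seed=7)
        assert a1 == a2
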