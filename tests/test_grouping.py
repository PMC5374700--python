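import math

import numpy as np
import pandas as pd
import pytest

from netmdc.datatypes import AnnotationTable, SampleMetadata
from netmdc.grouping import (
    CompoundSimilarityMatrix,
    adjusted_rand_index,
    build_aggregate_network,
    compound_similarity,
    compounds_with_min_replicates,
    cut_compound_tree,
    jaccard_protein_distance,
    mean_profile_distance,
)
from netmdc.modules import ModulePartition, cluster_modules
from netmdc.network import pearson_adjacency
from netmdc.synthetic import generate_cohort

from conftest import two_family_design


def brute_force_ari(labels1, labels2):
    """Independent oracle: pair counting over all unordered element pairs."""
    n = len(labels1)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same1 = labels1[i] == labels1[j]
            same2 = labels2[i] == labels2[j]
            if same1 and same2:
                n11 += 1
            elif same1:
                n10 += 1
            elif same2:
                n01 += 1
            else:
                n00 += 1
    num = 2 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return num / den if den else 1.0


def _partition(labels):
    labels = list(labels)
    return ModulePartition([f"g{i}" for i in range(len(labels))], labels)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        p = _partition([1, 1, 2, 2, 3, 3])
        assert adjusted_rand_index(p, p) == 1.0

    def test_label_invariance(self):
        p1 = _partition([1, 1, 2, 2, 3, 3])
        p2 = _partition([3, 3, 1, 1, 2, 2])
        assert adjusted_rand_index(p1, p2) == 1.0

    def test_six_element_worked_example_matches_pair_counting_oracle(self):
        l1 = [1, 1, 1, 2, 2, 2]
        l2 = [1, 1, 2, 2, 2, 2]
        assert adjusted_rand_index(_partition(l1), _partition(l2)) == pytest.approx(
            brute_force_ari(l1, l2)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_small_partitions(self, seed):
        rng = np.random.default_rng(seed)
        l1 = rng.integers(1, 4, size=12)
        l2 = rng.integers(1, 4, size=12)
        assert adjusted_rand_index(_partition(l1), _partition(l2)) == pytest.approx(
            brute_force_ari(list(l1), list(l2))
        )

    def test_null_mean_near_zero_over_permutations(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 2, 3, 4], 25)
        p1 = _partition(labels)
        vals = [
            adjusted_rand_index(p1, _partition(rng.permutation(labels)))
            for _ in range(500)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_unassigned_genes_excluded_by_default(self):
        p1 = _partition([1, 1, 2, 2, 0, 0])
        p2 = _partition([1, 1, 2, 2, 1, 2])
        assert adjusted_rand_index(p1, p2) == 1.0

    def test_different_universes_rejected(self):
        p1 = ModulePartition(["a", "b"], [1, 1])
        p2 = ModulePartition(["a", "c"], [1, 1])
        with pytest.raises(ValueError):
            adjusted_rand_index(p1, p2)


class TestCompoundSimilarityAndGrouping:
    def test_identical_partitions_give_all_ones(self):
        p = _partition([1] * 10 + [2] * 10)
        sim = compound_similarity({"c1": p, "c2": p, "c3": p})
        np.testing.assert_allclose(sim.values, 1.0)

    def test_single_compound(self):
        sim = compound_similarity({"c1": _partition([1, 1, 2, 2])})
        assert sim.values.shape == (1, 1)
        assert sim.values[0, 0] == 1.0

    def test_planted_families_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            x, meta, _ = generate_cohort(two_family_design(seed))
            parts = {
                c: cluster_modules(
                    pearson_adjacency(x.subset_samples(meta.samples_for(c))), 10, 4
                )
                for c in meta.compounds()
            }
            grouping = cut_compound_tree(compound_similarity(parts), 3, 4)
            planted = [0 if c.startswith("A") else 1 for c in grouping.compound_ids]
            assert adjusted_rand_score(planted, grouping.labels) > 0.9

    def test_min_group_size_respected(self):
        x, meta, _ = generate_cohort(two_family_design(1))
        parts = {
            c: cluster_modules(
                pearson_adjacency(x.subset_samples(meta.samples_for(c))), 10, 4
            )
            for c in meta.compounds()
        }
        grouping = cut_compound_tree(compound_similarity(parts), 3, 4)
        assert all(s >= 3 for s in grouping.group_sizes.values())

    def test_degenerate_all_identical_similarity_gives_single_group(self):
        n = 8
        sim = CompoundSimilarityMatrix(
            [f"c{i}" for i in range(n)], np.ones((n, n)), "ARI"
        )
        grouping = cut_compound_tree(sim, 3, 4)
        assert grouping.group_labels == [1]
        assert grouping.group_sizes[1] == n

    def test_too_few_compounds_rejected(self):
        sim = CompoundSimilarityMatrix(["a", "b"], np.ones((2, 2)), "ARI")
        with pytest.raises(ValueError):
            cut_compound_tree(sim, 3, 4)


class TestReplicateFilter:
    def test_threshold_applied(self, meta_two_compounds):
        assert compounds_with_min_replicates(meta_two_compounds, 3) == ["drugA"]
        assert compounds_with_min_replicates(meta_two_compounds, 2) == ["drugA", "drugB"]


class TestBaselines:
    def test_mean_profile_distance_zero_for_identical_compounds(self, family_cohort):
        x, meta, _ = family_cohort
        dist = mean_profile_distance(x, meta)
        assert dist.kind == "EXPR_EUCLID"
        np.testing.assert_allclose(np.diag(dist.values), 0.0)
        np.testing.assert_allclose(dist.values, dist.values.T)

    def test_single_gene_delta(self):
        import pandas as pd

        from netmdc.datatypes import ExpressionMatrix

        x = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 3.0, 3.0]], index=["g1"],
                         columns=["s1", "s2", "s3", "s4"])
        )
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["s1", "s2", "s3", "s4"],
            "compound": ["cA", "cA", "cB", "cB"],
        }))
        dist = mean_profile_distance(x, meta)
        assert dist.values[0, 1] == pytest.approx(2.0)

    def test_triangle_inequality_on_random_fixture(self):
        import pandas as pd

        from netmdc.datatypes import ExpressionMatrix

        rng = np.random.default_rng(4)
        n_comp = 5
        x = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(10, n_comp * 3)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(n_comp * 3)],
        ))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n_comp * 3)],
            "compound": [f"c{j // 3}" for j in range(n_comp * 3)],
        }))
        d = mean_profile_distance(x, meta).values
        for i in range(n_comp):
            for j in range(n_comp):
                for k in range(n_comp):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_jaccard_distance_formula(self):
        ann = AnnotationTable(pd.DataFrame({
            "compound": ["ci"] * 3 + ["ck"] * 3,
            "item": ["A", "B", "C", "B", "C", "D"],
        }))
        dist = jaccard_protein_distance(ann)
        assert dist.values[0, 1] == pytest.approx(0.5)

    def test_jaccard_identical_and_disjoint_sets(self):
        ann = AnnotationTable(pd.DataFrame({
            "compound": ["a", "a", "b", "b", "c", "c"],
            "item": ["p1", "p2", "p1", "p2", "p3", "p4"],
        }))
        dist = jaccard_protein_distance(ann)
        idx = {c: i for i, c in enumerate(dist.compound_ids)}
        assert dist.values[idx["a"], idx["b"]] == 0.0
        assert dist.values[idx["a"], idx["c"]] == 1.0


class TestAggregateNetwork:
    def test_single_compound_equals_plain_cn(self, family_cohort):
        x, meta, _ = family_cohort
        agg = build_aggregate_network(x, meta, ["A0"])
        plain = pearson_adjacency(x.subset_samples(meta.samples_for("A0")))
        np.testing.assert_allclose(agg.weights, plain.weights, atol=1e-10)

    def test_sample_count_bookkeeping(self, family_cohort):
        x, meta, _ = family_cohort
        agg = build_aggregate_network(x, meta, ["A0", "A1", "A2"])
        assert agg.n_samples == 75
        assert agg.flavor == "PARTIAL_CN"
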