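"""Rand index and the global / nodal permutation tests."""

import numpy as np
import pytest

from commpat.comparison import (
    _nodal_rand_tensor, group_permutation_test, node_community_labeling,
    nodal_permutation_test, pairwise_rand_matrix, rand_index,
    within_group_mean_rand,
)
from commpat.detection import Partition

from conftest import brute_rand, random_partition


def test_identical_partitions_rand_one(rng):
    p = random_partition(rng, 10, 4)
    assert rand_index(p, p) == 1.0


def test_hand_counted_examples():
    u = Partition((1, 1, 2, 2))
    v = Partition((1, 2, 1, 2))
    assert rand_index(u, v) == pytest.approx(1 / 3)
    singles = Partition((1, 2, 3))
    allinone = Partition((1, 1, 1))
    assert rand_index(singles, allinone) == 0.0


def test_mismatched_node_sets_rejected():
    with pytest.raises(ValueError):
        rand_index(Partition((1, 2)), Partition((1, 2, 3)))


def test_rand_matches_bruteforce_pair_counting(rng):
    for _ in range(100):
        n = int(rng.integers(2, 21))
        u = random_partition(rng, n, 6)
        v = random_partition(rng, n, 6)
        assert rand_index(u, v) == pytest.approx(brute_rand(u.assignment, v.assignment),
                                                 abs=1e-14)


def test_rand_symmetry_and_label_invariance(rng):
    u = random_partition(rng, 15, 5)
    v = random_partition(rng, 15, 5)
    assert rand_index(u, v) == rand_index(v, u)
    relabeled = Partition(tuple(7 - c for c in v.assignment))  # invert ids
    assert rand_index(u, relabeled) == pytest.approx(rand_index(u, v))


def test_within_group_mean_rand_examples():
    same = Partition((1, 1, 2, 2))
    u = Partition((1, 1, 2, 2))
    v = Partition((1, 2, 1, 2))
    per_group, pooled = within_group_mean_rand(
        [same, same, u, v], ["a", "a", "b", "b"])
    assert per_group["a"] == pytest.approx(1.0)
    assert per_group["b"] == pytest.approx(1 / 3)
    assert pooled == pytest.approx((1 + 1 / 3) / 2)


def test_all_identical_partitions_mean_one(rng):
    p = random_partition(rng, 8, 3)
    per_group, pooled = within_group_mean_rand([p] * 6, ["a"] * 3 + ["b"] * 3)
    assert pooled == 1.0


def test_single_subject_group_rejected(rng):
    parts = [random_partition(rng, 6, 3) for _ in range(3)]
    with pytest.raises(ValueError):
        within_group_mean_rand(parts, ["a", "b", "b"])


def test_degenerate_identical_partitions_strict_p_zero(rng):
    p = random_partition(rng, 8, 3)
    res = group_permutation_test([p] * 8, ["a"] * 4 + ["b"] * 4, 100, seed=1)
    assert res.observed_statistic == 1.0
    assert res.p_value == 0.0          # every null equals observed; strict rule
    nonstrict = group_permutation_test([p] * 8, ["a"] * 4 + ["b"] * 4, 100,
                                       seed=1, strict=False)
    assert nonstrict.p_value == 1.0


def test_perfectly_separated_groups_minimal_p(rng):
    a = Partition((1, 1, 1, 2, 2, 2))
    b = Partition((1, 2, 3, 1, 2, 3))
    res = group_permutation_test([a, a, a, b, b, b], ["x"] * 3 + ["y"] * 3, 500, seed=0)
    assert res.p_value <= 1 / res.n_permutations
    assert res.method == "enumerated"  # C(6,3) = 20 <= 500


def test_enumeration_matches_sampled_null_support(rng):
    parts = [random_partition(rng, 8, 3) for _ in range(6)]
    labels = ["x"] * 3 + ["y"] * 3
    enum = group_permutation_test(parts, labels, 1000, seed=3)
    samp = group_permutation_test(parts, labels, 19, seed=3)
    assert enum.method == "enumerated" and samp.method == "sampled"
    assert enum.observed_statistic == samp.observed_statistic


def test_precomputed_rand_matrix_changes_nothing(rng):
    parts = [random_partition(rng, 10, 4) for _ in range(8)]
    labels = ["x"] * 4 + ["y"] * 4
    direct = group_permutation_test(parts, labels, 200, seed=5)
    via_matrix = group_permutation_test(parts, labels, 200, seed=5,
                                        rand_matrix=pairwise_rand_matrix(parts))
    assert direct.to_dict() == via_matrix.to_dict()


def test_node_community_labeling_examples():
    part = Partition((1, 1, 2, 2))
    assert node_community_labeling(part, 0).tolist() == [1, 0, 0]
    singleton = Partition((1, 2, 2, 2))
    assert node_community_labeling(singleton, 0).tolist() == [0, 0, 0]
    with pytest.raises(ValueError):
        node_community_labeling(part, 9)


def test_nodal_tensor_matches_direct_rand(rng):
    """The vectorized per-node similarity equals Rand on induced labelings."""
    parts = [random_partition(rng, 9, 4) for _ in range(4)]
    tensor = _nodal_rand_tensor(parts)
    for x in range(9):
        for s in range(4):
            for t in range(s + 1, 4):
                u = node_community_labeling(parts[s], x)
                v = node_community_labeling(parts[t], x)
                assert tensor[x, s, t] == pytest.approx(brute_rand(u, v), abs=1e-12)


def test_nodal_test_deterministic_given_seed(rng):
    parts = [random_partition(rng, 12, 4) for _ in range(10)]
    labels = ["x"] * 5 + ["y"] * 5
    r1 = nodal_permutation_test(parts, labels, 200, seed=9)
    r2 = nodal_permutation_test(parts, labels, 200, seed=9)
    assert np.array_equal(r1.per_node_p, r2.per_node_p)
    assert np.all(r1.per_node_q >= r1.per_node_p)


def test_null_p_values_roughly_uniform(rng):
    """Under exchangeable partitions, p-values should be near-uniform."""
    reps = 60
    pvals = []
    for i in range(reps):
        parts = [random_partition(rng, 12, 4) for _ in range(12)]
        labels = ["x"] * 6 + ["y"] * 6
        res = group_permutation_test(parts, labels, 300, seed=1000 + i)
        pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    assert 0.0 <= np.mean(pvals < 0.05) <= 0.15
    assert abs(pvals.mean() - 0.5) < 0.12
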