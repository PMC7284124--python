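"""Partition indices, cross-validated k selection, permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphotype import (CohortSpec, HydraConfig, adjusted_rand_index,
                        cv_stability_sweep, generate_cohort, hamming_distance,
                        permutation_test, rand_index)
from morphotype.selection import permutation_pvalue

# ---------------------------------------------------------------------------
# independent oracles (pure-Python pair counting / bijection enumeration)


def ari_oracle(a, b):
    n = len(a)
    s11 = s_a = s_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            ta, tb = a[i] == a[j], b[i] == b[j]
            s11 += ta and tb
            s_a += ta
            s_b += tb
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    expected = s_a * s_b / total
    max_index = (s_a + s_b) / 2.0
    if max_index == expected:
        return 1.0
    return (s11 - expected) / (max_index - expected)


def rand_oracle(a, b):
    n = len(a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    total = n * (n - 1) // 2
    return agree / total if total else 1.0


def hamming_oracle(a, b):
    from itertools import permutations
    names_a = sorted(set(a))
    names_b = sorted(set(b))
    big = names_a + [f"pad{i}" for i in range(max(0, len(names_b) - len(names_a)))]
    small = names_b + [f"pad{i}" for i in range(max(0, len(names_a) - len(names_b)))]
    best = len(a)
    for perm in permutations(small):
        mapping = dict(zip(big, perm))
        mism = sum(1 for x, y in zip(a, b) if mapping[x] != y)
        best = min(best, mism)
    return best / len(a)


class TestIndexExamples:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert hamming_distance([1, 1, 2, 2], [1, 1, 2, 2]) == 0.0

    def test_label_renaming_is_absorbed(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0
        assert hamming_distance([1, 1, 2, 2], [2, 2, 1, 1]) == 0.0

    def test_single_disagreeing_pair(self):
        assert rand_index([1, 2], [1, 1]) == 0.0

    def test_known_hamming_value(self):
        assert hamming_distance([1, 1, 2, 2], [1, 2, 2, 2]) == 0.25

    def test_three_vs_two_cluster_ari_matches_pair_counting(self):
        a = [1, 1, 1, 2, 2, 2]
        b = [1, 1, 2, 2, 3, 3]
        assert adjusted_rand_index(a, b) == pytest.approx(ari_oracle(a, b), abs=1e-15)

    def test_length_mismatch_rejected(self):
        for fn in (adjusted_rand_index, rand_index, hamming_distance):
            with pytest.raises(ValueError):
                fn([1, 2], [1, 2, 3])

    def test_agreement_with_sklearn_cross_check(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12)

    def test_oracle_agreement_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            a = rng.integers(1, 5, n).tolist()
            b = rng.integers(1, 5, n).tolist()
            assert abs(adjusted_rand_index(a, b) - ari_oracle(a, b)) <= 1e-12
            assert abs(rand_index(a, b) - rand_oracle(a, b)) <= 1e-12
            assert abs(hamming_distance(a, b) - hamming_oracle(a, b)) <= 1e-12


label_pairs = st.integers(2, 20).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(1, 4), min_size=n, max_size=n),
        st.lists(st.integers(1, 4), min_size=n, max_size=n)))


class TestIndexProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(label_pairs)
    def test_symmetry(self, pair):
        a, b = pair
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a), abs=1e-12)
        assert rand_index(a, b) == pytest.approx(rand_index(b, a), abs=1e-12)
        assert hamming_distance(a, b) == pytest.approx(hamming_distance(b, a), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(label_pairs)
    def test_bounds_and_perfection_equivalence(self, pair):
        a, b = pair
        ari = adjusted_rand_index(a, b)
        ri = rand_index(a, b)
        hd = hamming_distance(a, b)
        assert ari <= 1.0 + 1e-12
        assert 0.0 <= ri <= 1.0
        assert 0.0 <= hd <= 1.0
        # ARI = 1 iff Rand = 1 iff Hamming = 0 (identical partitions)
        assert (ari == 1.0) == (ri == 1.0) == (hd == 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(label_pairs)
    def test_renaming_invariance(self, pair):
        a, b = pair
        renamed = [{1: 4, 2: 3, 3: 2, 4: 1}[x] for x in a]
        assert adjusted_rand_index(a, b) == adjusted_rand_index(renamed, b)
        assert hamming_distance(a, b) == hamming_distance(renamed, b)


class TestPermutationPvalue:
    def test_observed_above_all_null(self):
        assert permutation_pvalue(1.0, np.zeros(99)) == pytest.approx(0.01)

    def test_all_ties_give_one(self):
        assert permutation_pvalue(0.5, np.full(99, 0.5)) == 1.0

    def test_never_zero(self):
        assert permutation_pvalue(np.inf, np.zeros(10)) > 0.0


class TestCvStabilitySweep:
    def test_two_folds_single_pair_sd_zero(self, planted_cohort):
        _, features, records, _ = planted_cohort
        rep = cv_stability_sweep(features, records, [2], n_folds=2,
                                 config=HydraConfig(n_restarts=3, seed=0))
        assert rep.ari_sd[2] == 0.0
        assert rep.selected_k == 2

    def test_planted_structure_selects_k2_and_beats_noise(self, planted_cohort,
                                                          null_cohort):
        _, features, records, _ = planted_cohort
        rep = cv_stability_sweep(features, records, [2, 3], n_folds=5,
                                 config=HydraConfig(n_restarts=8, seed=1))
        assert rep.selected_k == 2
        assert rep.ari_mean[2] > 0.8
        _, nf, nr, _ = null_cohort
        null_rep = cv_stability_sweep(nf, nr, [2, 3], n_folds=5,
                                      config=HydraConfig(n_restarts=8, seed=1))
        assert max(null_rep.ari_mean.values()) < rep.ari_mean[2]

    def test_fold_too_small_rejected(self, null_cohort):
        _, features, records, _ = null_cohort
        with pytest.raises(ValueError):
            cv_stability_sweep(features, records, [46], n_folds=10,
                               config=HydraConfig(n_restarts=1, seed=0))

    def test_report_invariants(self, planted_cohort):
        _, features, records, _ = planted_cohort
        rep = cv_stability_sweep(features, records, [2, 3], n_folds=4,
                                 config=HydraConfig(n_restarts=3, seed=2))
        assert rep.selected_k in rep.k_values
        for k in rep.k_values:
            assert rep.ari_mean[k] <= 1.0 + 1e-12
            assert 0.0 <= rep.hamming_mean[k] <= 1.0
            assert 0.0 <= rep.rand_mean[k] <= 1.0


class TestPermutationTest:
    def test_planted_structure_is_significant(self, planted_cohort):
        _, features, records, _ = planted_cohort
        p, null = permutation_test(features, records, 2, n_permutations=19,
                                   config=HydraConfig(n_restarts=2, seed=3),
                                   n_folds=5)
        assert p <= 0.05
        assert null.shape == (19,)

    def test_deterministic(self, null_cohort):
        _, features, records, _ = null_cohort
        cfg = HydraConfig(n_restarts=1, max_iterations=10, seed=8)
        p1, n1 = permutation_test(features, records, 2, 5, cfg, n_folds=3)
        p2, n2 = permutation_test(features, records, 2, 5, cfg, n_folds=3)
        assert p1 == p2
        np.testing.assert_array_equal(n1, n2)
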