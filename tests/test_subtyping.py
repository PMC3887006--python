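import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import roc_auc_score

from regsubtype.snea import weighted_mann_whitney
from regsubtype.subtyping import (
    adjusted_rand_index,
    auc,
    bootstrap_stability,
    cluster_samples,
    fisher_criterion,
    pearson_distance,
    permutation_pvalue,
    rand_index,
    stable_feature_selection,
)


class TestPearsonDistance:
    def test_identical_vectors_give_zero(self):
        v = [1.0, 2.0, 5.0]
        assert pearson_distance(v, v) == pytest.approx(0.0)

    def test_anticorrelated_vectors_give_two(self):
        assert pearson_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_uncorrelated_vectors_give_one(self):
        a = [1.0, -1.0, 1.0, -1.0]
        b = [1.0, 1.0, -1.0, -1.0]  # r = 0 by construction
        assert pearson_distance(a, b) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_distance([1, 1, 1], [1, 2, 3])


class TestClusterSamples:
    def _features(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        cols = {}
        for i in range(4):
            cols[f"a{i}"] = base + rng.normal(0, 0.05, 6)
        for i in range(4):
            cols[f"b{i}"] = -base + rng.normal(0, 0.05, 6)
        return pd.DataFrame(cols)

    def test_anticorrelated_groups_separate_at_k2(self):
        sc = cluster_samples(self._features(), k="auto", k_range=(2, 5))
        assert sc.k == 2
        labs = sc.sample_labels
        assert len({labs[f"a{i}"] for i in range(4)}) == 1
        assert labs["a0"] != labs["b0"]

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k"):
            cluster_samples(self._features(), k=1)

    def test_duplicated_samples_cocluster(self):
        f = self._features()
        f["a_dup"] = f["a0"]
        for k in (2, 3, 4):
            sc = cluster_samples(f, k=k)
            assert sc.sample_labels["a_dup"] == sc.sample_labels["a0"]

    def test_constant_profile_names_sample(self):
        f = self._features()
        f["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(f, k=2)


def _hubert_arabie(a, b):
    """Independent ARI oracle straight from the contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    cats_a, cats_b = sorted(set(a)), sorted(set(b))
    n = len(a)
    table = np.array([[np.sum((a == ca) & (b == cb)) for cb in cats_b]
                      for ca in cats_a])
    sum_ij = sum(comb(nij, 2) for nij in table.ravel())
    sum_a = sum(comb(x, 2) for x in table.sum(axis=1))
    sum_b = sum(comb(x, 2) for x in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


class TestRandIndices:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_renaming_invariance(self):
        assert adjusted_rand_index([1, 1, 2, 2], ["x", "x", "y", "y"]) == 1.0

    def test_crossed_partition_is_minus_half(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)
        assert _hubert_arabie(a, b) == pytest.approx(-0.5)

    def test_matches_contingency_oracle_on_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 4, size=20)
            b = rng.integers(0, 3, size=20)
            assert adjusted_rand_index(a, b) == pytest.approx(
                _hubert_arabie(a, b), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=15)
        b = rng.integers(0, 3, size=15)
        assert adjusted_rand_index(a, b) == adjusted_rand_index(b, a)

    def test_mapping_input_aligned_by_sample(self):
        a = {"s1": 1, "s2": 1, "s3": 2}
        b = {"s3": "y", "s1": "x", "s2": "x"}
        assert adjusted_rand_index(a, b) == 1.0

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({"s1": 1, "s2": 2}, {"s1": 1, "s3": 2})

    def test_raw_rand_of_identical_partition_is_one(self):
        assert rand_index([1, 2, 1], [5, 6, 5]) == 1.0


class TestBootstrapStability:
    def _separated(self, n_per=6):
        rng = np.random.default_rng(3)
        base = rng.normal(size=8)
        cols = {f"a{i}": base + rng.normal(0, 0.01, 8) for i in range(n_per)}
        cols |= {f"b{i}": -base + rng.normal(0, 0.01, 8) for i in range(n_per)}
        f = pd.DataFrame(cols)
        ref = pd.Series({s: s[0] for s in f.columns})
        return f, ref

    def test_perfect_separation_gives_mean_one_and_zero_width_ci(self):
        f, ref = self._separated()
        res = bootstrap_stability(f, ref, n_runs=50, fraction=0.9, k=2, seed=0)
        assert res.mean == 1.0
        assert res.ci95_low == res.ci95_high == 1.0
        # every sample always lands in its reference cluster
        assert np.allclose(res.assignment_frequency.max(axis=1), 1.0)

    def test_random_labels_on_noise_give_near_zero_ari(self):
        rng = np.random.default_rng(4)
        f = pd.DataFrame(rng.normal(size=(8, 24)),
                         columns=[f"s{i}" for i in range(24)])
        ref = pd.Series(rng.integers(0, 2, 24), index=f.columns)
        res = bootstrap_stability(f, ref, n_runs=300, fraction=0.9, k=2, seed=5)
        assert abs(res.mean) < 0.05

    def test_same_seed_reproduces_ari_vector(self):
        f, ref = self._separated()
        r1 = bootstrap_stability(f, ref, n_runs=20, k=2, seed=7)
        r2 = bootstrap_stability(f, ref, n_runs=20, k=2, seed=7)
        assert np.array_equal(r1.ari_values, r2.ari_values)

    def test_full_fraction_gives_degenerate_distribution(self):
        f, ref = self._separated()
        res = bootstrap_stability(f, ref, n_runs=10, fraction=1.0, k=2, seed=8)
        assert len(set(res.ari_values.tolist())) == 1

    def test_mean_inside_ci(self):
        f, ref = self._separated()
        f2 = f + np.random.default_rng(9).normal(0, 0.5, f.shape)
        res = bootstrap_stability(f2, ref, n_runs=100, k=2, seed=9)
        assert res.ci95_low <= res.mean <= res.ci95_high

    def test_bad_fraction_rejected(self):
        f, ref = self._separated()
        with pytest.raises(ValueError):
            bootstrap_stability(f, ref, fraction=1.5, k=2)


class TestFisherCriterion:
    def test_hand_value(self):
        # means 1 and 0, each sample variance 0.5
        a = [0.0, 1.0, 2.0]  # mean 1, var 1 → scale to var 0.5
        a = [1 - math.sqrt(0.5), 1.0, 1 + math.sqrt(0.5)]
        b = [-math.sqrt(0.5), 0.0, math.sqrt(0.5)]
        assert fisher_criterion(a, b) == pytest.approx(1.0)

    def test_identical_classes_give_zero(self):
        assert fisher_criterion([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_degenerate_separation_is_infinite(self):
        assert fisher_criterion([0.0, 0.0], [1.0, 1.0]) == math.inf

    def test_degenerate_equal_constant_classes_give_zero(self):
        assert fisher_criterion([1.0, 1.0], [1.0, 1.0]) == 0.0


class TestPermutationPvalue:
    def test_perfect_separation_matches_exhaustive_enumeration(self):
        values = [10.0, 11.0, 0.0, 1.0]
        labels = ["a", "a", "b", "b"]
        # C(4,2)=6 label assignments; 2 (identity and swap) reach F >= obs
        f_obs = fisher_criterion([10.0, 11.0], [0.0, 1.0])
        n_extreme = 0
        from itertools import combinations
        for pos in combinations(range(4), 2):
            a = [values[i] for i in pos]
            b = [values[i] for i in range(4) if i not in pos]
            if fisher_criterion(a, b) >= f_obs:
                n_extreme += 1
        assert n_extreme == 2
        p = permutation_pvalue(values, labels, n_perm=3000, seed=0)
        assert p == pytest.approx(2 / 6, abs=0.03)

    def test_add_one_estimator_never_zero(self):
        p = permutation_pvalue([10, 11, 12, 0, 1, 2], ["a"] * 3 + ["b"] * 3,
                               n_perm=99, seed=1)
        assert p >= 1 / 100

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=12)
        lab = ["a"] * 6 + ["b"] * 6
        assert permutation_pvalue(v, lab, n_perm=200, seed=3) == \
               permutation_pvalue(v, lab, n_perm=200, seed=3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3], ["a", "a", "a"])


class TestAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], ["n", "n", "p", "p"], 1.0),
            ([1, 3, 2, 4], ["n", "n", "p", "p"], 0.75),
            ([2, 2, 2, 2], ["n", "n", "p", "p"], 0.5),
        ],
    )
    def test_values(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_equals_normalized_u_and_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n0 = rng.integers(2, 10, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # ties likely
            labels = np.array(["p"] * n1 + ["n"] * n0)
            a = auc(scores, labels, pos_label="p")
            u, _ = weighted_mann_whitney(
                scores[labels == "p"], np.ones(n1, int),
                scores[labels == "n"], np.ones(n0, int),
            )
            assert a == pytest.approx(u / (n1 * n0), abs=1e-12)
            assert a == pytest.approx(
                roc_auc_score((labels == "p").astype(int), scores), abs=1e-12
            )


class TestStableFeatureSelection:
    def _activity(self, seed=0, shift=3.0):
        rng = np.random.default_rng(seed)
        cols = [f"a{i}" for i in range(15)] + [f"b{i}" for i in range(15)]
        labels = pd.Series({s: s[0] for s in cols})
        data = pd.DataFrame(rng.normal(size=(3, 30)), columns=cols,
                            index=["planted", "noise1", "noise2"])
        data.loc["planted", [c for c in cols if c[0] == "a"]] += shift
        return data, labels

    def test_planted_cluster_selected_with_full_stability(self):
        data, labels = self._activity()
        res = stable_feature_selection(data, labels, n_runs=30, n_perm=199, seed=1)
        assert "planted" in res.selected
        assert res.table.loc["planted", "stability_fraction"] == 1.0
        assert res.table.loc["planted", "auc"] in (0.0, 1.0) or \
            abs(res.table.loc["planted", "auc"] - 0.5) > 0.45

    def test_noise_cluster_not_selected(self):
        data, labels = self._activity(seed=2)
        res = stable_feature_selection(data, labels, n_runs=30, n_perm=199, seed=3)
        assert "noise1" not in res.selected
        assert "noise2" not in res.selected

    def test_alpha_one_selects_everything(self):
        data, labels = self._activity(seed=4)
        res = stable_feature_selection(data, labels, n_runs=10, n_perm=49,
                                       alpha=1.0, seed=5)
        assert set(res.selected) == set(data.index)

    def test_auc_reported_only_for_selected(self):
        data, labels = self._activity(seed=6)
        res = stable_feature_selection(data, labels, n_runs=30, n_perm=199, seed=7)
        unselected = res.table.index[~res.table["selected"]]
        assert res.table.loc[unselected, "auc"].isna().all()
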