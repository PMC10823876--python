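"""SFV statistic: analytic cases, brute-force equivalence, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgvdi import (
    LabeledFeatureSet,
    between_dispersion,
    class_means,
    class_stds,
    sfv_score,
    within_dispersion,
)


def brute_force_sfv(matrix, labels):
    """Independent oracle: explicit loops over the defining sums.

    Class means and population stds per feature, D as the weighted double
    sum of pairwise Euclidean distances between class mean vectors, c as
    the grand mean of all class-feature stds.
    """
    classes = sorted(set(labels))
    K = len(classes)
    I = matrix.shape[1]
    means, stds = [], []
    for k in classes:
        rows = [matrix[r] for r in range(len(labels)) if labels[r] == k]
        J = len(rows)
        mu = [sum(row[i] for row in rows) / J for i in range(I)]
        sd = [
            math.sqrt(sum((row[i] - mu[i]) ** 2 for row in rows) / J)
            for i in range(I)
        ]
        means.append(mu)
        stds.append(sd)
    dist_sum = 0.0
    for p in range(K - 1):
        for q in range(p + 1, K):
            dist_sum += math.sqrt(
                sum((means[p][i] - means[q][i]) ** 2 for i in range(I))
            )
    D = 2.0 / (K * (K - 1)) * dist_sum
    c = sum(stds[k][i] for k in range(K) for i in range(I)) / (I * K)
    return D, c, D / c if c > 0 else float("inf")


def make_set(matrix, labels):
    return LabeledFeatureSet(np.asarray(matrix, float), np.asarray(labels))


class TestClassStatistics:
    def test_class_means_arithmetic(self):
        fs = make_set([[0.0, 0.0], [1.0, 1.0], [0.4, 0.6]], [1, 1, 2])
        m = class_means(fs)
        np.testing.assert_allclose(m, [[0.5, 0.5], [0.4, 0.6]])

    def test_single_sample_class_mean_is_sample_std_zero(self):
        fs = make_set([[0.3], [0.9]], [1, 2])
        np.testing.assert_allclose(class_means(fs), [[0.3], [0.9]])
        np.testing.assert_allclose(class_stds(fs), [[0.0], [0.0]])

    def test_population_std_divisor(self):
        fs = make_set([[0.0], [1.0]], [1, 1, ][:2])
        # one class with rows 0 and 1: population std = 0.5
        fs = make_set([[0.0], [1.0], [0.5]], [1, 1, 2])
        np.testing.assert_allclose(class_stds(fs)[0], [0.5])

    def test_sample_std_switch(self):
        fs = make_set([[0.0], [1.0], [0.5]], [1, 1, 2])
        with pytest.raises(ValueError, match="ddof"):
            class_stds(fs, ddof=1)  # singleton class cannot use ddof=1
        fs2 = make_set([[0.0], [1.0], [0.5], [0.7]], [1, 1, 2, 2])
        np.testing.assert_allclose(
            class_stds(fs2, ddof=1)[0], [np.std([0, 1], ddof=1)]
        )


class TestDispersions:
    def test_two_class_single_pair(self):
        assert between_dispersion([[0.1], [0.9]]) == pytest.approx(0.8)

    def test_three_class_average(self):
        # pairwise distances 1, 2, 1 -> (2/6) * 4 = 4/3
        assert between_dispersion([[0.0], [1.0], [2.0]]) == pytest.approx(4 / 3)

    def test_identical_means_give_zero(self):
        assert between_dispersion([[0.5, 0.5]] * 3) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            between_dispersion([[0.5]])

    @pytest.mark.parametrize(
        "stds,expected",
        [
            ([[0.1], [0.1]], 0.1),
            ([[0.0], [0.0]], 0.0),
            ([[0.3, 0.3, 0.3], [0.3, 0.3, 0.3]], 0.3),
        ],
    )
    def test_within_dispersion_grand_mean(self, stds, expected):
        assert within_dispersion(stds) == pytest.approx(expected)


class TestSfvScore:
    def test_worked_one_dimensional_example(self):
        """Class A {0, 0.2}, class B {0.8, 1.0}: D = 0.8, c = 0.1, SFV = 8."""
        fs = make_set([[0.0], [0.2], [0.8], [1.0]], [1, 1, 2, 2])
        comp = sfv_score(fs)
        assert comp.D == pytest.approx(0.8, rel=1e-12)
        assert comp.c == pytest.approx(0.1, rel=1e-12)
        assert comp.sfv == pytest.approx(8.0, rel=1e-12)

    def test_label_permutation_invariance(self):
        fs1 = make_set([[0.0], [0.2], [0.8], [1.0]], [1, 1, 2, 2])
        fs2 = make_set([[0.0], [0.2], [0.8], [1.0]], [5, 5, 3, 3])
        assert sfv_score(fs1).sfv == pytest.approx(sfv_score(fs2).sfv)

    def test_identical_means_nonzero_spread_gives_zero(self):
        fs = make_set([[0.0], [1.0], [0.0], [1.0]], [1, 1, 2, 2])
        assert sfv_score(fs).sfv == 0.0

    def test_collapsed_clusters_flagged_infinite(self):
        fs = make_set([[0.1], [0.9]], [1, 2])
        comp = sfv_score(fs)
        assert comp.infinite and comp.sfv == float("inf")

    def test_all_identical_undefined(self):
        fs = make_set([[0.5], [0.5]], [1, 2])
        with pytest.raises(ValueError, match="SFV undefined"):
            sfv_score(fs)

    def test_scale_and_translation_invariance(self, rng):
        x = rng.random((30, 4))
        labels = rng.integers(1, 4, 30)
        base = sfv_score(make_set(x, labels)).sfv
        scaled = sfv_score(
            make_set(0.37 * x, labels), check_range=False
        ).sfv
        shifted = sfv_score(
            make_set(x + 5.0, labels), check_range=False
        ).sfv
        assert scaled == pytest.approx(base, rel=1e-12)
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_feature_permutation_invariance(self, rng):
        x = rng.random((20, 5))
        labels = rng.integers(1, 4, 20)
        perm = rng.permutation(5)
        assert sfv_score(make_set(x[:, perm], labels)).sfv == pytest.approx(
            sfv_score(make_set(x, labels)).sfv, rel=1e-12
        )

    def test_moving_a_mean_outward_does_not_decrease_D(self):
        means = np.array([[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]])
        centroid_others = means[:2].mean(axis=0)
        d0 = between_dispersion(means)
        moved = means.copy()
        moved[2] = centroid_others + 1.5 * (means[2] - centroid_others)
        assert between_dispersion(moved) >= d0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        I = int(rng.integers(1, 7))
        labels = np.concatenate(
            [np.full(int(rng.integers(1, 11)), k) for k in range(1, K + 1)]
        )
        x = rng.random((labels.size, I))
        comp = sfv_score(make_set(x, labels))
        D, c, sfv = brute_force_sfv(x, list(labels))
        assert comp.D == pytest.approx(D, rel=1e-12)
        assert comp.c == pytest.approx(c, rel=1e-12)
        assert comp.sfv == pytest.approx(sfv, rel=1e-12)
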