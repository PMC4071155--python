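"""Bayes and linear classifiers, Wald test and its power."""

import itertools

import numpy as np
import pytest

from snpvus import (
    MAFProfile,
    build_bayes,
    build_linear,
    mle_theta,
    simulate_genotypes,
    table1_design,
    wald_power,
    wald_test,
)
from snpvus.classifiers import BayesSNPClassifier


def _enumerate_genotypes(l):
    return np.array(list(itertools.product((0, 1, 2), repeat=l)))


class TestBayesClassifier:
    def test_pairwise_coefficient_value(self):
        prof = MAFProfile(theta=np.array([[0.4], [0.2]]))
        clf = build_bayes(prof)
        expected = np.log((0.4 * 0.8) / (0.2 * 0.6))
        assert np.isclose(clf.coef_[0, 1, 0], expected)

    def test_identical_classes_give_null_rule(self):
        prof = MAFProfile(theta=np.full((3, 5), 0.3))
        clf = build_bayes(prof)
        assert np.allclose(clf.coef_, 0)
        assert np.allclose(clf.thresholds_, 0)

    @pytest.mark.parametrize("D,l,seed", [(2, 5, 0), (2, 6, 1), (3, 4, 2), (3, 5, 3)])
    def test_pairwise_rule_equals_posterior_argmax(self, D, l, seed):
        # exhaustive enumeration: the pairwise-threshold rule must assign
        # exactly the class with the largest posterior, for every genotype
        # vector, including under non-uniform priors
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.05, 0.45, size=(D, l))
        priors = rng.dirichlet(np.ones(D) * 5)
        clf = BayesSNPClassifier(theta=theta, priors=priors).fit()
        X = _enumerate_genotypes(l)
        labels, _ = clf.classify(X)
        post = clf.posterior_log_scores(X)
        np.testing.assert_array_equal(labels, post.argmax(axis=1) + 1)

    def test_pairwise_margins_antisymmetric(self):
        prof = table1_design(3, 0.08, 12, seed=4)
        clf = build_bayes(prof)
        X = simulate_genotypes(prof, 30, seed=1).values
        m = clf.pairwise_margins(X)
        np.testing.assert_allclose(m, -np.swapaxes(m, 1, 2), atol=1e-10)

    def test_classification_accuracy_on_separated_design(self):
        prof = table1_design(3, 0.15, 100, seed=5)
        clf = build_bayes(prof)
        data = simulate_genotypes(prof, 2000, seed=6)
        labels, _ = clf.classify(data.values)
        assert (labels == data.labels).mean() > 0.9

    def test_near_identical_classes_assign_uniformly(self):
        # with (near-)indistinguishable classes the tie rule should not
        # favour any class; tiny MAF jitter avoids exact-tie degeneracy
        rng = np.random.default_rng(7)
        base = rng.uniform(0.25, 0.35, size=30)
        theta = base[None, :] + rng.normal(scale=1e-3, size=(3, 30))
        clf = BayesSNPClassifier(theta=theta).fit()
        X = np.random.default_rng(8).binomial(2, base, size=(6000, 30))
        labels, _ = clf.classify(X)
        rates = np.bincount(labels, minlength=4)[1:] / len(labels)
        assert np.abs(rates - 1 / 3).max() < 0.05

    def test_dimension_mismatch_rejected(self):
        clf = build_bayes(table1_design(2, 0.1, 6, seed=0))
        with pytest.raises(ValueError):
            clf.classify(np.zeros((3, 4), dtype=int))


class TestMleTheta:
    def test_counting_and_clipping(self):
        X = np.array([[1, 0], [2, 0]])
        y = np.array([1, 2])
        theta, n_k, classes = mle_theta(X, y)
        # single sample per class: clip bounds are [0.25, 0.75]
        assert theta[0, 0] == 0.5
        assert theta[0, 1] == 0.25  # all-zero column clipped, not 0
        assert theta[1, 0] == 0.75  # x=2 gives 1.0, capped
        np.testing.assert_array_equal(n_k, [1, 1])

    def test_consistency_at_large_n(self):
        n = 10_000
        prof = MAFProfile(theta=np.full((1, 1), 0.3))
        data = simulate_genotypes(prof, n, seed=3)
        theta, _, _ = mle_theta(data.values, data.labels)
        assert abs(theta[0, 0] - 0.3) < 3 * np.sqrt(0.3 * 0.7 / (2 * n))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            mle_theta(np.zeros((2, 1)), [1, 1], classes=[1, 2])


class TestWald:
    def test_null_point_never_rejects(self):
        z, rej = wald_test(0.3, 0.3, 100, 100, alpha=0.1)
        assert z == 0 and not rej

    def test_empirical_size_matches_level(self, rng):
        n, alpha, reps = 200, 0.1, 10_000
        c1 = rng.binomial(2 * n, 0.3, size=reps) / (2 * n)
        c2 = rng.binomial(2 * n, 0.3, size=reps) / (2 * n)
        _, rej = wald_test(c1, c2, n, n, alpha)
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rej.mean() - alpha) < 3 * se

    def test_power_formula_matches_simulation(self, rng):
        n, alpha, reps = 100, 0.1, 10_000
        t1, t2 = 0.45, 0.30
        c1 = rng.binomial(2 * n, t1, size=reps) / (2 * n)
        c2 = rng.binomial(2 * n, t2, size=reps) / (2 * n)
        _, rej = wald_test(c1, c2, n, n, alpha)
        analytic = wald_power(t1 - t2, t1, n, n, alpha)
        assert abs(rej.mean() - analytic) < 0.02

    def test_power_size_and_monotonicity(self):
        assert np.isclose(wald_power(0.0, 0.3, 50, 50, 0.1), 0.1)
        powers = [wald_power(0.1, 0.4, n, n, 0.05) for n in (10, 50, 250, 1250, 6000)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            wald_power(0.5, 0.4, 50, 50, 0.1)


class TestLinearClassifier:
    def test_false_positive_weight_count_under_null(self):
        # identical classes: each (j, pair) weight is a level-alpha false
        # positive; the total count concentrates around alpha * m * pairs
        m, n, alpha = 200, 300, 0.05
        prof = MAFProfile(theta=np.full((3, m), 0.3))
        data = simulate_genotypes(prof, n, seed=11)
        clf = build_linear(data, alpha=alpha)
        n_tests = m * 3  # unordered class pairs for D=3
        count = clf.weights_[np.triu_indices(3, 1)].sum()
        assert abs(count - alpha * n_tests) < 3 * np.sqrt(n_tests * alpha * (1 - alpha))

    def test_consistency_toward_bayes_rule(self):
        prof = table1_design(3, 0.15, 30, seed=12)
        data = simulate_genotypes(prof, 5000, seed=13)
        clf = build_linear(data, alpha=0.1)
        assert clf.weights_[np.triu_indices(3, 1)].all()
        bayes = build_bayes(prof)
        # b_hat sd per entry ~ 0.03 at n=5000; 4 sd across 90 entries
        np.testing.assert_allclose(clf.coef_, bayes.coef_, atol=0.12)

    def test_strong_single_snp_is_weighted(self):
        theta = np.array([[0.45, 0.3], [0.1, 0.3]])
        data = simulate_genotypes(MAFProfile(theta=theta), 200, seed=14)
        clf = build_linear(data, alpha=0.1)
        assert clf.weights_[0, 1, 0]

    def test_weight_symmetry(self):
        prof = table1_design(3, 0.05, 20, seed=15)
        data = simulate_genotypes(prof, 60, seed=16)
        clf = build_linear(data)
        np.testing.assert_array_equal(clf.weights_, np.swapaxes(clf.weights_, 0, 1))

    def test_sklearn_predict_interface(self):
        prof = table1_design(2, 0.15, 40, seed=17)
        data = simulate_genotypes(prof, 300, seed=18)
        clf = build_linear(data)
        pred = clf.predict(data.values)
        assert pred.shape == data.labels.shape
        assert clf.score(data.values, data.labels) > 0.8
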