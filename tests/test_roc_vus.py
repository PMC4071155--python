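"""Operating points, AUC, and the VUS threshold-search engine."""

import numpy as np
import pytest
from scipy.special import ndtr

from snpvus import (
    MAFProfile,
    SearchParams,
    StudyDesign,
    auc,
    build_bayes,
    operating_point,
    simulate_genotypes,
    table1_design,
    vus,
    vus_empirical,
)
from snpvus.pcc import GaussianApprox, class_approxes
from snpvus.roc_vus import EmpiricalXi, GaussianXi, hull_volume

FAST = SearchParams(n_init=256, batch=128, min_iter=4)


def _binormal_evaluator(mu1, sd1, mu2, sd2):
    """Two classes with 1-d Gaussian scores and centered thresholds."""
    a1 = GaussianApprox(np.array([mu1]), np.array([[sd1**2]]), np.zeros(1), 0, (1,))
    a2 = GaussianApprox(np.array([mu2]), np.array([[sd2**2]]), np.zeros(1), 1, (0,))
    return GaussianXi([a1, a2])


def grid_vus_d3(evaluator, n_grid=200):
    """Brute-force VUS oracle: Riemann integration of xi_3 against the
    threshold-to-rate Jacobian on a regular (K1, K2) grid.

    Independent of the stochastic search / convex hull path: the volume is
    the change-of-variables integral of xi_3 |d(xi_1, xi_2)/d(K1, K2)|.
    """
    B = evaluator.box_halfwidth
    ax = np.linspace(-B, B, n_grid)
    K1, K2 = np.meshgrid(ax, ax, indexing="ij")
    kvecs = np.column_stack([K1.ravel(), K2.ravel()])
    xi = evaluator(kvecs).reshape(n_grid, n_grid, 3)
    d11, d12 = np.gradient(xi[:, :, 0], ax, ax)
    d21, d22 = np.gradient(xi[:, :, 1], ax, ax)
    jac = np.abs(d11 * d22 - d12 * d21)
    step = ax[1] - ax[0]
    return float((xi[:, :, 2] * jac).sum() * step * step)


class TestHullVolume:
    @pytest.mark.parametrize(
        "points, expected",
        [
            (np.eye(3), 1 / 6),  # unit simplex
            (np.eye(4), 1 / 24),
            (np.ones((1, 3)), 1.0),  # full cube
            (np.ones((1, 4)), 1.0),
            # box [0,(1,1,.5)] plus the pyramid up to the e3 anchor
            (np.array([[1.0, 1.0, 0.5]]), 0.5 + 1 / 6),
        ],
    )
    def test_analytic_values(self, points, expected):
        assert abs(hull_volume(points) - expected) < 1e-6


class TestOperatingPoints:
    def test_roc_endpoints_d2(self):
        ev = _binormal_evaluator(1.0, 1.0, 1.0, 1.0)
        lo = operating_point([-50.0], ev)
        hi = operating_point([50.0], ev)
        np.testing.assert_allclose(lo.xi, [1, 0], atol=1e-9)
        np.testing.assert_allclose(hi.xi, [0, 1], atol=1e-9)

    def test_identical_classes_symmetric_at_zero(self, identical_profile_d3):
        ev = GaussianXi(class_approxes(identical_profile_d3, variant="infty"))
        op = operating_point([0.0, 0.0], ev)
        assert np.allclose(op.xi, op.xi[0], atol=1e-6)

    def test_separated_design_all_rates_high_at_zero(self, profile_d3):
        ev = GaussianXi(class_approxes(profile_d3, variant="infty"))
        op = operating_point([0.0, 0.0], ev)
        assert (op.xi > 0.5).all()
        assert op.contributes


class TestAuc:
    def test_identical_classes_chance_level(self):
        prof = MAFProfile(theta=np.full((2, 30), 0.3))
        ev = GaussianXi(class_approxes(prof, variant="infty"))
        assert abs(auc(ev) - 0.5) < 0.005

    def test_binormal_closed_form(self):
        mu1, sd1, mu2, sd2 = 1.3, 1.1, 0.7, 0.9
        ev = _binormal_evaluator(mu1, sd1, mu2, sd2)
        expected = ndtr((mu1 + mu2) / np.hypot(sd1, sd2))
        assert abs(auc(ev) - expected) < 1e-3

    def test_perfect_separation(self):
        assert auc(_binormal_evaluator(30, 1, 30, 1)) > 0.999

    def test_requires_two_classes(self, profile_d3):
        ev = GaussianXi(class_approxes(profile_d3, variant="infty"))
        with pytest.raises(ValueError):
            auc(ev)


class TestVusSearch:
    def test_random_classifier_floor_d3(self, identical_profile_d3):
        ev = GaussianXi(class_approxes(identical_profile_d3, variant="infty"))
        res = vus(ev, FAST, seed=0)
        assert abs(res.volume - 1 / 6) < 0.02

    def test_random_classifier_floor_d4(self):
        prof = MAFProfile(theta=np.full((4, 30), 0.3))
        ev = GaussianXi(class_approxes(prof, variant="infty"))
        res = vus(ev, SearchParams(n_init=1024, batch=512, min_iter=4), seed=0)
        assert abs(res.volume - 1 / 24) < 0.02

    def test_perfect_classifier_reaches_one(self):
        approxes = [
            GaussianApprox(np.full(2, 60.0), np.eye(2), np.zeros(2), k,
                           tuple(i for i in range(3) if i != k))
            for k in range(3)
        ]
        res = vus(GaussianXi(approxes), FAST, seed=1)
        assert abs(res.volume - 1.0) < 0.02

    def test_agrees_with_grid_integration_oracle(self, profile_d3):
        ev = GaussianXi(class_approxes(profile_d3, variant="infty"))
        stochastic = vus(ev, seed=2).volume
        riemann = grid_vus_d3(ev)
        assert abs(stochastic - riemann) < 0.01

    def test_reproducible_and_monotone_history(self, profile_d3):
        ev = GaussianXi(class_approxes(profile_d3, variant="infty"))
        r1 = vus(ev, FAST, seed=42)
        r2 = vus(ev, FAST, seed=42)
        assert r1.volume == r2.volume
        np.testing.assert_array_equal(r1.points, r2.points)
        assert all(b >= a for a, b in zip(r1.history, r1.history[1:]))

    def test_volume_within_theoretical_bounds(self, profile_d3):
        ev = GaussianXi(class_approxes(profile_d3, variant="infty"))
        res = vus(ev, FAST, seed=3)
        assert 1 / 6 - 0.02 <= res.volume <= 1.0

    def test_rejects_two_class_problems(self):
        prof = MAFProfile(theta=np.full((2, 10), 0.3))
        with pytest.raises(ValueError):
            vus(GaussianXi(class_approxes(prof, variant="infty")), FAST, seed=0)


class TestVusEmpirical:
    def test_empirical_rates_match_orthant_rates(self, profile_d3):
        clf = build_bayes(profile_d3)
        test = simulate_genotypes(profile_d3, 4000, seed=9)
        emp = EmpiricalXi(clf, test)(np.zeros((1, 2)))[0]
        ana = GaussianXi(class_approxes(profile_d3, variant="infty"))(
            np.zeros((1, 2))
        )[0]
        se = np.sqrt(ana * (1 - ana) / 4000)
        assert (np.abs(emp - ana) < 3 * se + 0.01).all()

    def test_single_class_test_data_rejected(self, profile_d3):
        clf = build_bayes(profile_d3)
        data = simulate_genotypes(profile_d3, 50, seed=10)
        keep = data.labels == 1
        from snpvus.design import GenotypeMatrix

        one = GenotypeMatrix(values=data.values[keep], labels=data.labels[keep])
        with pytest.raises(ValueError):
            vus_empirical(clf, one, FAST, seed=0)

    def test_close_to_analytic_vus_for_bayes_rule(self, profile_d3):
        clf = build_bayes(profile_d3)
        test = simulate_genotypes(profile_d3, 1500, seed=11)
        emp = vus_empirical(clf, test, FAST, seed=4).volume
        ana = vus(GaussianXi(class_approxes(profile_d3, variant="infty")),
                  FAST, seed=4).volume
        assert abs(emp - ana) < 0.05
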