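"""Gaussian approximations to the probability of correct classification.

For class k, the D-1 pairwise scores S_{k,k'} = sum_j b_{k,k'}^j X_j are
sums of many independent bounded terms, so for large l they are jointly
approximately Gaussian.  The per-class correct-classification rate is then
the orthant probability

    xi_k = P(S_{k,k'} > K_{k,k'} for all k' != k | X in C_k)
         ~ P(Z > Kvec_k),   Z ~ N(mu_k, Sigma_k) in D-1 dimensions,

and PCC = sum_k pi_k xi_k.  Two variants are provided:

* ``infty`` -- the optimal Bayes rule with the true MAFs (PCC(infinity));
* ``n`` -- the Wald-weighted plug-in rule fitted from n_k samples per class
  (PCC(n)), whose moments account for (i) each SNP entering a contrast with
  probability equal to the Wald test's power at its MAF difference and
  (ii) first-order (delta-method) estimation noise in the plug-in log-odds
  coefficients, with the shared theta_hat_k term inducing covariance across
  contrasts of the same class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal, qmc

from .classifiers import BayesSNPClassifier, build_bayes, wald_power
from .design import MAFProfile, StudyDesign

__all__ = [
    "GaussianApprox",
    "gaussian_approx_infty",
    "gaussian_approx_n",
    "class_approxes",
    "orthant_probability",
    "orthant_probability_batch",
    "pcc",
]

#: default absolute tolerance for the numerical MVN CDF
DEFAULT_ABSEPS = 1e-4
#: quasi-MC node count for the batched Genz tail routine (dim >= 3)
_GENZ_NODES = 512
_CLIP = 1e-14


@dataclass(frozen=True)
class GaussianApprox:
    """(D-1)-dimensional normal approximation of one class's pairwise scores.

    ``mu``/``sigma`` are the mean vector and covariance of the scores
    against the other classes (in the order ``others``); ``kvec`` holds the
    matching thresholds.  ``variant`` is "infty" (true MAFs) or "n"
    (estimation-adjusted moments).
    """

    mu: np.ndarray
    sigma: np.ndarray
    kvec: np.ndarray
    class_index: int
    others: tuple
    variant: str = "infty"


def _jittered(sigma: np.ndarray) -> np.ndarray:
    d = sigma.shape[0]
    jitter = 1e-10 * np.trace(sigma) / d + 1e-12
    return sigma + jitter * np.eye(d)


def _safe_cholesky(sigma: np.ndarray) -> np.ndarray:
    sig = _jittered(sigma)
    for _ in range(6):
        try:
            return cholesky(sig, lower=True)
        except np.linalg.LinAlgError:
            sig = sig + 10 * np.abs(np.trace(sig)) / sig.shape[0] * 1e-8 * np.eye(
                sig.shape[0]
            )
    raise np.linalg.LinAlgError("covariance not positive semidefinite after jitter")


def _genz_nodes(dim: int, n: int = _GENZ_NODES) -> np.ndarray:
    # fixed scramble seed: the nodes are a deterministic quadrature rule
    sob = qmc.Sobol(d=dim, scramble=True, seed=20140614)
    return sob.random(n)


def _mvn_tail_genz(mu, chol_l, thresholds, nodes) -> np.ndarray:
    """Quasi-MC separation-of-variables estimate of P(Z > t) per row of t."""
    a = np.atleast_2d(thresholds) - mu  # (M, d)
    d = a.shape[1]
    lo = a[:, 0] / chol_l[0, 0]
    d_prev = ndtr(lo)  # (M,)
    f = (1.0 - d_prev)[:, None] * np.ones((1, nodes.shape[0]))
    di = d_prev[:, None]
    y = np.empty((a.shape[0], nodes.shape[0], d - 1))
    for i in range(1, d):
        u = nodes[None, :, i - 1]
        y[:, :, i - 1] = ndtri(np.clip(di + u * (1.0 - di), _CLIP, 1 - _CLIP))
        partial = np.einsum("mnj,j->mn", y[:, :, :i], chol_l[i, :i])
        di = ndtr((a[:, i, None] - partial) / chol_l[i, i])
        f = f * (1.0 - di)
    return f.mean(axis=1)


def orthant_probability_batch(mu, sigma, thresholds) -> np.ndarray:
    """Vectorized P(Z > t componentwise), Z ~ N(mu, sigma), t row-wise.

    Dimension 1 uses the exact normal tail; dimension 2 scipy's bivariate
    CDF; higher dimensions a Genz quasi-MC tail with fixed Sobol nodes
    (deterministic, abs. error ~1e-4 for well-conditioned covariances).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    t = np.atleast_2d(np.asarray(thresholds, dtype=float))
    d = mu.size
    if d == 1:
        sd = np.sqrt(_jittered(sigma)[0, 0])
        return ndtr((mu[0] - t[:, 0]) / sd)
    if d == 2:
        sig = _jittered(sigma)
        return multivariate_normal(mean=np.zeros(2), cov=sig).cdf(-(t - mu))
    return _mvn_tail_genz(mu, _safe_cholesky(sigma), t, _genz_nodes(d - 1))


def orthant_probability(approx: GaussianApprox, abseps: float = DEFAULT_ABSEPS):
    """xi_k = P(Z > kvec componentwise) for Z ~ N(mu, sigma).

    Uses the exact univariate tail in one dimension and scipy's numerical
    multivariate normal CDF otherwise (absolute tolerance ``abseps``);
    rank-deficient covariances get a diagonal jitter of
    1e-10 * tr(sigma)/(D-1).
    """
    mu, kvec = approx.mu, approx.kvec
    d = mu.size
    if d == 1:
        sd = np.sqrt(_jittered(approx.sigma)[0, 0])
        return float(ndtr((mu[0] - kvec[0]) / sd))
    sigma = _jittered(approx.sigma)
    if np.linalg.eigvalsh(sigma).min() < 0:
        raise np.linalg.LinAlgError("covariance not PSD after jitter")
    dist = multivariate_normal(mean=np.zeros(d), cov=sigma, abseps=abseps)
    return float(np.clip(dist.cdf(mu - kvec), 0.0, 1.0))


def gaussian_approx_infty(classifier: BayesSNPClassifier, class_k: int):
    """Normal approximation of class ``class_k``'s pairwise Bayes scores.

    Under X_j ~ Binomial(2, theta_kj), score S_{k,k'} has mean
    sum_j b 2 theta_kj and covariance sum_j b b' 2 theta_kj (1 - theta_kj)
    across contrasts (shared X_j).  ``class_k`` is 0-based.
    """
    theta = classifier.profile_.theta[:, : classifier.l_]
    D = theta.shape[0]
    k = int(class_k)
    others = tuple(kp for kp in range(D) if kp != k)
    b = classifier.coef_[k][list(others)]  # (D-1, l)
    mean_x = 2.0 * theta[k]
    var_x = 2.0 * theta[k] * (1.0 - theta[k])
    mu = b @ mean_x
    sigma = (b * var_x) @ b.T
    kvec = classifier.thresholds_[k][list(others)]
    return GaussianApprox(mu, sigma, kvec, k, others, "infty")


def gaussian_approx_n(profile: MAFProfile, design: StudyDesign):
    """Estimation-adjusted normal approximation for every class (PCC(n)).

    For the contrast (k, k'), each SNP j contributes w_j b_hat_j X_j where
    w_j ~ Bernoulli(power of the level-alpha Wald test at h_j) and b_hat_j
    is the plug-in coefficient with delta-method variance
    1/(2 n_k theta_kj (1-theta_kj)) + 1/(2 n_k' theta_k'j (1-theta_k'j)).
    Inclusion is treated as independent across SNPs and contrasts; the two
    contrasts of a class share theta_hat_k, giving the cross-contrast
    coefficient covariance 1/(2 n_k theta_kj (1-theta_kj)).  Thresholds use
    the power-weighted plug-in form.  Returns one GaussianApprox per class;
    all moments converge to the ``infty`` variant as every n_k grows.
    """
    theta, priors = profile.theta, profile.priors
    D, m = theta.shape
    n = design.n
    if n.size != D:
        raise ValueError("design.n_per_class must give a size for every class")
    logit = np.log(theta) - np.log1p(-theta)
    log1m = np.log1p(-theta)
    out = []
    for k in range(D):
        others = tuple(kp for kp in range(D) if kp != k)
        mean_x = 2.0 * theta[k]
        var_x = 2.0 * theta[k] * (1.0 - theta[k])
        ex2 = var_x + mean_x**2
        v_shared = 1.0 / (2.0 * n[k] * theta[k] * (1.0 - theta[k]))
        bs, ps, vs = [], [], []
        kvec = np.empty(D - 1)
        for i, kp in enumerate(others):
            h = theta[k] - theta[kp]
            p = wald_power(h, theta[k], n[k], n[kp], design.alpha)
            b = logit[k] - logit[kp]
            v = v_shared + 1.0 / (2.0 * n[kp] * theta[kp] * (1.0 - theta[kp]))
            bs.append(b)
            ps.append(p)
            vs.append(v)
            kvec[i] = np.log(priors[kp] / priors[k]) + (
                2.0 * p * (log1m[kp] - log1m[k])
            ).sum()
        mu = np.empty(D - 1)
        sigma = np.empty((D - 1, D - 1))
        for i in range(D - 1):
            mu[i] = (ps[i] * bs[i] * mean_x).sum()
            sigma[i, i] = (
                ps[i] * (bs[i] ** 2 + vs[i]) * ex2
                - ps[i] ** 2 * bs[i] ** 2 * mean_x**2
            ).sum()
            for j in range(i + 1, D - 1):
                cov = (
                    ps[i] * ps[j] * (bs[i] * bs[j] * var_x + v_shared * ex2)
                ).sum()
                sigma[i, j] = sigma[j, i] = cov
        out.append(GaussianApprox(mu, sigma, kvec, k, others, "n"))
    return out


def class_approxes(profile: MAFProfile, design: StudyDesign | None = None, variant="infty"):
    """Per-class GaussianApprox list for either variant.

    ``variant="infty"`` builds the optimal Bayes classifier (using
    l = floor(rho m) SNPs when a design is given); ``variant="n"`` requires
    a design carrying per-class sample sizes and the Wald level.
    """
    if variant == "infty":
        l = design.l if design is not None else None
        clf = build_bayes(profile, l=l)
        return [gaussian_approx_infty(clf, k) for k in range(profile.D)]
    if variant == "n":
        if design is None:
            raise ValueError("variant 'n' requires a StudyDesign with sample sizes")
        return gaussian_approx_n(profile, design)
    raise ValueError(f"unknown variant {variant!r}")


def pcc(approxes, priors=None) -> float:
    """PCC = sum_k pi_k xi_k from per-class Gaussian approximations."""
    if priors is None:
        priors = np.full(len(approxes), 1.0 / len(approxes))
    priors = np.asarray(priors, dtype=float)
    xis = np.array([orthant_probability(a) for a in approxes])
    return float(np.clip((priors * xis).sum(), 0.0, 1.0))
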