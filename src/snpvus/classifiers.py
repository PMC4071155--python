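"""Optimal Bayes and Wald-weighted linear classifiers for coded SNP data.

Both classifiers score a genotype vector x (codes 0/1/2) through pairwise
log-odds contrasts: class k beats class k' when

    sum_j b_{k,k'}^j x_j > K_{k,k'},

with b_{k,k'}^j = log[ theta_{k,j} (1 - theta_{k',j}) /
                      (theta_{k',j} (1 - theta_{k,j})) ]

and threshold K_{k,k'} = log(pi_{k'}/pi_k)
                         + sum_j 2 log[(1 - theta_{k',j}) / (1 - theta_{k,j})].

With the true minor allele frequencies theta this pairwise rule is exactly
the Bayes (posterior argmax) rule under HWE and independent SNPs.  The
linear classifier plugs in maximum-likelihood estimates and keeps SNP j in
the (k, k') contrast only when a level-alpha Wald test rejects equality of
the two MAFs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .design import GenotypeMatrix, MAFProfile

__all__ = [
    "BayesSNPClassifier",
    "LinearSNPClassifier",
    "mle_theta",
    "wald_test",
    "wald_power",
    "build_bayes",
    "build_linear",
    "classify",
]


def _check_codes(X, m: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X))
    if X.shape[1] != m:
        raise ValueError(f"expected {m} SNP columns, got {X.shape[1]}")
    if not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotype codes must be 0, 1 or 2")
    return X.astype(float)


def pairwise_coefficients(theta: np.ndarray) -> np.ndarray:
    """b[k, k', j] = log odds-ratio contrast between classes k and k'."""
    logit = np.log(theta) - np.log1p(-theta)
    return logit[:, None, :] - logit[None, :, :]


def pairwise_thresholds(theta: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """K[k, k'] = log(pi_k'/pi_k) + sum_j 2 log((1-theta_k'j)/(1-theta_kj))."""
    log1m = np.log1p(-theta).sum(axis=1)
    prior_part = np.log(priors)[None, :] - np.log(priors)[:, None]
    return prior_part + 2.0 * (log1m[None, :] - log1m[:, None])


class _PairwiseSNPClassifier(ClassifierMixin, BaseEstimator):
    """Shared prediction machinery over fitted pairwise scores/thresholds.

    Fitted subclasses provide ``coef_`` (D x D x m, antisymmetric in the
    class axes), ``thresholds_`` (D x D) and ``classes_``.
    """

    def _effective_coef(self) -> np.ndarray:
        return self.coef_

    def pairwise_margins(self, X, offsets=None) -> np.ndarray:
        """Margins M[i, k, k'] = S_{k,k'}(x_i) - K_{k,k'} (- offset shift).

        ``offsets`` is an optional length-D vector of per-class threshold
        offsets; the (k, k') threshold is shifted by offsets[k'] - offsets[k].
        This is the family of operating points swept to trace the ROC
        hypersurface (equivalently, a sweep of the class priors).
        """
        check_is_fitted(self, "coef_")
        X = _check_codes(X, self.coef_.shape[2])
        scores = np.einsum("ij,klj->ikl", X, self._effective_coef())
        margins = scores - self.thresholds_[None, :, :]
        if offsets is not None:
            offsets = np.asarray(offsets, dtype=float)
            margins = margins - (offsets[None, None, :] - offsets[None, :, None])
        return margins

    def decision_function(self, X) -> np.ndarray:
        """Per-class worst pairwise margin min_{k' != k} (S - K)."""
        margins = self.pairwise_margins(X)
        D = margins.shape[1]
        margins[:, np.arange(D), np.arange(D)] = np.inf
        return margins.min(axis=2)

    def predict(self, X) -> np.ndarray:
        labels, _ = self.classify(X)
        return labels

    def classify(self, X, offsets=None):
        """Assign each sample; flag those with no strict pairwise winner.

        A sample is unflagged when one class wins all D-1 pairwise
        comparisons strictly.  Otherwise the tie rule assigns
        argmax_k min_{k'} margin (smallest class index on residual ties)
        and the sample is flagged.
        """
        margins = self.pairwise_margins(X, offsets=offsets)
        D = margins.shape[1]
        margins[:, np.arange(D), np.arange(D)] = np.inf
        worst = margins.min(axis=2)
        idx = worst.argmax(axis=1)
        flagged = worst.max(axis=1) <= 0.0
        return self.classes_[idx], flagged


class BayesSNPClassifier(_PairwiseSNPClassifier):
    """Optimal Bayes classifier from known per-class MAFs under HWE.

    Parameters
    ----------
    theta : (D, m) array or MAFProfile
        Per-class minor allele frequencies.
    priors : length-D array, optional
        Class priors; uniform by default.
    l : int, optional
        Number of leading SNPs with marginal effect used by the rule
        (defaults to all m).
    """

    def __init__(self, theta=None, priors=None, l=None):
        self.theta = theta
        self.priors = priors
        self.l = l

    def fit(self, X=None, y=None):
        """Build pairwise coefficients and thresholds (no data needed)."""
        if isinstance(self.theta, MAFProfile):
            profile = self.theta
            if self.priors is not None:
                profile = MAFProfile(theta=profile.theta, priors=self.priors)
        else:
            profile = MAFProfile(theta=self.theta, priors=self.priors)
        l = profile.m if self.l is None else int(self.l)
        if not 1 <= l <= profile.m:
            raise ValueError(f"l={l} outside [1, m={profile.m}]")
        theta_l = profile.theta[:, :l]
        self.profile_ = profile
        self.l_ = l
        self.coef_ = pairwise_coefficients(theta_l)
        self.thresholds_ = pairwise_thresholds(theta_l, profile.priors)
        self.classes_ = np.arange(1, profile.D + 1)
        self.n_features_in_ = l
        return self

    def posterior_log_scores(self, X) -> np.ndarray:
        """Unnormalized log posterior log pi_k + log f_k(x) per class."""
        check_is_fitted(self, "coef_")
        X = _check_codes(X, self.l_)
        th = self.profile_.theta[:, : self.l_]
        return (
            np.log(self.profile_.priors)[None, :]
            + X @ np.log(th).T
            + (2.0 - X) @ np.log1p(-th).T
        )


def mle_theta(X, y, classes=None, clip: bool = True):
    """Per-class MLE minor allele frequencies from coded genotypes.

    theta_hat[k, j] = (sum of codes in class k at SNP j) / (2 n_k), clipped
    to [1/(4 n_k), 1 - 1/(4 n_k)] so that log-odds coefficients stay finite.
    Returns ``(theta_hat, n_k, classes)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    theta = np.empty((len(classes), X.shape[1]))
    n_k = np.empty(len(classes), dtype=int)
    for k, c in enumerate(classes):
        rows = X[y == c]
        if rows.shape[0] == 0:
            raise ValueError(f"class {c!r} has no samples")
        n_k[k] = rows.shape[0]
        theta[k] = rows.sum(axis=0) / (2.0 * n_k[k])
        if clip:
            lo = 1.0 / (4.0 * n_k[k])
            theta[k] = np.clip(theta[k], lo, 1.0 - lo)
    return theta, n_k, np.asarray(classes)


def wald_test(theta_hat_k, theta_hat_kp, n_k, n_kp, alpha: float):
    """Two-sample Wald test of equal MAFs from 2n alleles per class.

    Z = (th_k - th_k') / sqrt(th_k(1-th_k)/(2n_k) + th_k'(1-th_k')/(2n_k')),
    rejecting when |Z| > z_{1-alpha/2}.  Vectorized over SNPs; returns
    ``(statistic, reject)``.  A zero-variance comparison (both estimates
    clipped to the same boundary) yields Z = 0 and no rejection.
    """
    t1 = np.asarray(theta_hat_k, dtype=float)
    t2 = np.asarray(theta_hat_kp, dtype=float)
    var = t1 * (1 - t1) / (2 * n_k) + t2 * (1 - t2) / (2 * n_kp)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (t1 - t2) / np.sqrt(var), 0.0)
    crit = ndtri(1.0 - alpha / 2.0)
    return z, np.abs(z) > crit


def wald_power(h, theta_k, n_k, n_kp, alpha: float):
    """Normal-approximation power of the two-sided Wald MAF test.

    For a true difference h = theta_k - theta_k',

        1 - beta = Phi(-z_{1-a/2} + |h|/sigma) + Phi(-z_{1-a/2} - |h|/sigma),
        sigma^2 = theta_k(1-theta_k)/(2 n_k) + theta_k'(1-theta_k')/(2 n_k').

    At h = 0 the power equals the size alpha; it is monotone in |h| and n.
    """
    h = np.asarray(h, dtype=float)
    t1 = np.asarray(theta_k, dtype=float)
    t2 = t1 - h
    if ((t1 <= 0) | (t1 >= 1) | (t2 <= 0) | (t2 >= 1)).any():
        raise ValueError("theta_k and theta_k - h must lie in (0, 1)")
    sigma = np.sqrt(t1 * (1 - t1) / (2 * n_k) + t2 * (1 - t2) / (2 * n_kp))
    zc = ndtri(1.0 - alpha / 2.0)
    shift = np.abs(h) / sigma
    return ndtr(-zc + shift) + ndtr(-zc - shift)


class LinearSNPClassifier(_PairwiseSNPClassifier):
    """Plug-in pairwise classifier with Wald-test SNP weights.

    ``fit`` estimates per-class MAFs by maximum likelihood, then for every
    SNP j and class pair (k, k') runs a level-``alpha`` Wald test of equal
    MAFs; SNP j enters the (k, k') contrast (binary weight w = 1) only on
    rejection.  Thresholds use the plug-in estimates restricted to the
    weighted SNPs, keeping score and threshold on the same SNP subset.

    Parameters
    ----------
    alpha : per-SNP Wald test level (default 0.1).
    priors : length-D class priors; uniform by default.
    """

    def __init__(self, alpha: float = 0.1, priors=None):
        self.alpha = alpha
        self.priors = priors

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X))
        theta, n_k, classes = mle_theta(X, y)
        D, m = theta.shape
        if D < 2:
            raise ValueError("need at least 2 classes")
        priors = (
            np.full(D, 1.0 / D)
            if self.priors is None
            else np.asarray(self.priors, dtype=float)
        )
        weights = np.zeros((D, D, m), dtype=bool)
        for k in range(D):
            for kp in range(k + 1, D):
                _, rej = wald_test(theta[k], theta[kp], n_k[k], n_k[kp], self.alpha)
                weights[k, kp] = weights[kp, k] = rej
        coef = pairwise_coefficients(theta)
        # thresholds restricted to the Wald-selected SNPs of each pair
        log1m = np.log1p(-theta)
        thresholds = np.log(priors)[None, :] - np.log(priors)[:, None]
        for k in range(D):
            for kp in range(D):
                if k != kp:
                    w = weights[k, kp]
                    thresholds[k, kp] += 2.0 * (log1m[kp, w] - log1m[k, w]).sum()
        self.classes_ = classes
        self.theta_hat_ = theta
        self.n_per_class_ = n_k
        self.priors_ = priors
        self.weights_ = weights
        self.coef_ = coef
        self.thresholds_ = thresholds
        self.n_features_in_ = m
        return self

    def _effective_coef(self) -> np.ndarray:
        return self.coef_ * self.weights_


def build_bayes(profile: MAFProfile, l: int | None = None) -> BayesSNPClassifier:
    """Fit the optimal Bayes classifier from a MAF profile."""
    return BayesSNPClassifier(theta=profile, l=l).fit()


def build_linear(
    data: GenotypeMatrix, priors=None, alpha: float = 0.1
) -> LinearSNPClassifier:
    """Fit the Wald-weighted linear classifier from labelled genotype data."""
    return LinearSNPClassifier(alpha=alpha, priors=priors).fit(
        data.values, data.labels
    )


def classify(classifier, X, offsets=None):
    """Assign samples with a fitted classifier; see ``classify`` method."""
    return classifier.classify(X, offsets=offsets)
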