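"""Greedy extraction of pairwise-independent SNPs via Kendall's tau.

Classification assumes statistically independent SNPs, but dense genotype
panels are heavily correlated (linkage disequilibrium).  The screen below
keeps one representative per correlated group: scanning candidates in
order, a SNP joins the selected set S only if its tie-corrected Kendall
tau-b against every current member of S stays below a cutoff (default
|tau| < 0.05, read as a statistic cutoff; an alternative p-value mode
declares independence when the tau test fails to reject at the cutoff
level).  The greedy loop stops when every remaining SNP conflicts with at
least one member of S, so S is maximal for the given scan order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .design import GenotypeMatrix

__all__ = [
    "SelectionResult",
    "kendall_tau",
    "select_independent",
    "IndependentSNPSelector",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of the greedy independence screen.

    ``selected`` is the ordered list of retained SNP ids; ``rejected`` maps
    each excluded SNP to the first member of S that conflicted with it;
    ``tau`` records every pairwise statistic examined.
    """

    selected: list
    threshold: float
    mode: str
    rejected: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    selected_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b between two genotype columns.

    0/1/2-coded data is massively tied, so the tie-corrected tau-b is used.
    A constant column has undefined tau; it is reported as 0.0 (treated as
    independent) with a logged warning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("columns must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant genotype column: Kendall tau undefined, using 0")
        return 0.0
    return float(stats.kendalltau(x, y).statistic)


def _independent(x, y, threshold: float, mode: str) -> tuple[bool, float]:
    if mode == "statistic":
        tau = kendall_tau(x, y)
        return abs(tau) < threshold, tau
    if mode == "pvalue":
        if np.all(x == x[0]) or np.all(y == y[0]):
            return True, 0.0
        res = stats.kendalltau(x, y)
        return res.pvalue >= threshold, float(res.statistic)
    raise ValueError(f"mode must be 'statistic' or 'pvalue', got {mode!r}")


def select_independent(
    data: GenotypeMatrix | np.ndarray,
    threshold: float = 0.05,
    order_policy: str = "input",
    mode: str = "statistic",
) -> SelectionResult:
    """Greedy scan keeping SNPs pairwise independent under the tau screen.

    ``order_policy`` is "input" (column order, the default, reproducible)
    or "maf" (descending in-sample minor allele frequency).
    """
    if isinstance(data, GenotypeMatrix):
        values, ids = data.values, list(data.snp_ids)
    else:
        values = np.atleast_2d(np.asarray(data))
        ids = [f"snp{j + 1}" for j in range(values.shape[1])]
    m = values.shape[1]
    if m < 1:
        raise ValueError("need at least one SNP column")
    if order_policy == "input":
        order = np.arange(m)
    elif order_policy == "maf":
        maf = values.mean(axis=0) / 2.0
        maf = np.minimum(maf, 1.0 - maf)
        order = np.argsort(-maf, kind="stable")
    else:
        raise ValueError(f"unknown order_policy {order_policy!r}")
    selected: list[int] = []
    result = SelectionResult(selected=[], threshold=threshold, mode=mode)
    for j in order:
        conflict = None
        for s in selected:
            ok, tau = _independent(values[:, j], values[:, s], threshold, mode)
            result.tau[(ids[s], ids[j])] = tau
            if not ok:
                conflict = s
                break
        if conflict is None:
            selected.append(int(j))
        else:
            result.rejected[ids[j]] = ids[conflict]
    result.selected = [ids[j] for j in selected]
    result.selected_indices = np.array(selected, dtype=int)
    return result


class IndependentSNPSelector(SelectorMixin, BaseEstimator):
    """sklearn transformer applying the greedy tau independence screen.

    Parameters mirror :func:`select_independent`; after ``fit`` the mask of
    retained columns is available as ``support_`` / ``get_support()`` and
    the full report as ``result_``.
    """

    def __init__(self, threshold: float = 0.05, order_policy: str = "input",
                 mode: str = "statistic"):
        self.threshold = threshold
        self.order_policy = order_policy
        self.mode = mode

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X))
        res = select_independent(
            X, threshold=self.threshold, order_policy=self.order_policy,
            mode=self.mode,
        )
        self.result_ = res
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[res.selected_indices] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
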