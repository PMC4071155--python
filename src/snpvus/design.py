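"""Genotype model, study designs, and simulators for coded SNP data.

SNPs are biallelic loci coded 0/1/2 = number of copies of the minor allele.
Under Hardy-Weinberg equilibrium (HWE) the coded genotype at a locus with
minor allele frequency (MAF) theta is Binomial(2, theta).  A *MAF profile*
is the D x m matrix of per-class MAFs together with class priors; it fully
specifies the population model from which classifiers and their performance
surfaces are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StudyDesign",
    "MAFProfile",
    "GenotypeMatrix",
    "hwe_pmf",
    "simulate_genotypes",
    "table1_design",
    "correlated_fixture",
    "MAF_FLOOR",
    "MAF_CEIL",
]

#: admissible MAF range: below 0.01 a variant is treated as a mutation,
#: at or above 0.5 the allele is no longer the minor one.
MAF_FLOOR = 0.01
MAF_CEIL = 0.5


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class StudyDesign:
    """Design parameters for a classification / sample-size study.

    Parameters
    ----------
    D : number of classes (>= 2).
    m : number of statistically independent SNPs used for classification.
    n_per_class : per-class sample sizes n_1..n_D (an int broadcasts to all).
    rho : fraction of the m SNPs with a marginal effect; l = floor(rho * m)
        SNPs enter the optimal Bayes rule.
    alpha : level of the per-SNP Wald test that sets the linear classifier's
        binary weights.
    p_total : optional total SNP count before the independence filter.
    seed : RNG seed recorded with the design.
    """

    D: int
    m: int
    n_per_class: tuple = ()
    rho: float = 1.0
    alpha: float = 0.1
    p_total: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.D < 2:
            raise ValueError(f"need at least 2 classes, got D={self.D}")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        n = np.atleast_1d(np.asarray(self.n_per_class, dtype=int))
        if n.size == 1:
            n = np.repeat(n, self.D)
        if n.size not in (0, self.D):
            raise ValueError("n_per_class must be scalar or length D")
        if n.size and (n < 1).any():
            raise ValueError("all per-class sample sizes must be >= 1")
        object.__setattr__(self, "n_per_class", tuple(int(v) for v in n))
        if not 1 <= self.l <= self.m:
            raise ValueError(f"l=floor(rho*m)={self.l} outside [1, m={self.m}]")

    @property
    def l(self) -> int:
        """Number of SNPs with marginal effect, floor(rho * m)."""
        return int(np.floor(self.rho * self.m))

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.n_per_class, dtype=int)


@dataclass(frozen=True)
class MAFProfile:
    """Per-class minor allele frequencies theta (D x m) and class priors."""

    theta: np.ndarray
    priors: np.ndarray = None

    def __post_init__(self):
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "theta", theta)
        D = theta.shape[0]
        priors = self.priors
        if priors is None:
            priors = np.full(D, 1.0 / D)
        priors = np.asarray(priors, dtype=float)
        object.__setattr__(self, "priors", priors)
        if priors.shape != (D,):
            raise ValueError("priors must have one entry per class")
        if (priors < 0).any() or not np.isclose(priors.sum(), 1.0):
            raise ValueError("priors must be nonnegative and sum to 1")
        bad = (theta <= MAF_FLOOR) | (theta >= MAF_CEIL)
        if bad.any():
            k, j = np.argwhere(bad)[0]
            raise ValueError(
                f"theta[{k},{j}]={theta[k, j]:.4g} outside the admissible "
                f"MAF range ({MAF_FLOOR}, {MAF_CEIL})"
            )

    @property
    def D(self) -> int:
        return self.theta.shape[0]

    @property
    def m(self) -> int:
        return self.theta.shape[1]


@dataclass
class GenotypeMatrix:
    """Coded genotype table: values in {0,1,2}, one class label per row."""

    values: np.ndarray
    labels: np.ndarray
    snp_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d samples x SNPs matrix")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must have one entry per sample")
        if not self.snp_ids:
            self.snp_ids = [f"snp{j + 1}" for j in range(self.values.shape[1])]
        elif len(self.snp_ids) != self.values.shape[1]:
            raise ValueError("snp_ids length must match number of SNP columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def hwe_pmf(theta: float) -> np.ndarray:
    """Hardy-Weinberg genotype distribution over codes {0, 1, 2}.

    P(X = x) = C(2, x) theta^x (1 - theta)^(2 - x), i.e. Binomial(2, theta).
    """
    theta = float(theta)
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie strictly in (0, 1), got {theta}")
    q = 1.0 - theta
    return np.array([q * q, 2.0 * theta * q, theta * theta])


def simulate_genotypes(profile: MAFProfile, n_per_class, seed=None) -> GenotypeMatrix:
    """Draw i.i.d. HWE genotypes for each class of a MAF profile.

    Rows for class k are independent across samples and SNPs, with
    X_j ~ Binomial(2, theta[k, j]).  Class labels are 1..D.
    """
    rng = _as_rng(seed)
    n = np.atleast_1d(np.asarray(n_per_class, dtype=int))
    if n.size == 1:
        n = np.repeat(n, profile.D)
    if n.size != profile.D or (n < 1).any():
        raise ValueError("n_per_class must give a positive size for each class")
    blocks, labels = [], []
    for k in range(profile.D):
        blocks.append(rng.binomial(2, profile.theta[k], size=(n[k], profile.m)))
        labels.append(np.full(n[k], k + 1))
    return GenotypeMatrix(
        values=np.vstack(blocks).astype(np.int8), labels=np.concatenate(labels)
    )


def table1_design(D: int, h: float, m: int, seed=None) -> MAFProfile:
    """Simulation design with classes separated by a per-SNP MAF shift ~ h.

    theta_{1,j} ~ U(0.4, 0.49); each subsequent class k+1 has
    theta_{k+1,j} = theta_{k,j} - h_{k,j} with h_{k,j} ~ U(h-0.002, h+0.002).
    Priors are uniform.  Raises if any frequency would fall to the 0.01
    mutation floor (designs are rejected, never clipped).
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    rng = _as_rng(seed)
    theta = np.empty((D, m))
    theta[0] = rng.uniform(0.40, 0.49, size=m)
    for k in range(1, D):
        shift = rng.uniform(h - 0.002, h + 0.002, size=m)
        theta[k] = theta[k - 1] - shift
        low = theta[k] <= MAF_FLOOR
        if low.any():
            j = int(np.argmax(low))
            raise ValueError(
                f"design infeasible: theta[{k},{j}]={theta[k, j]:.4g} <= "
                f"{MAF_FLOOR} (h={h} too large for D={D})"
            )
    return MAFProfile(theta=theta)


def correlated_fixture(
    m_independent: int,
    m_redundant: int,
    noise: float = 0.0,
    n_samples: int = 500,
    maf_range: tuple = (0.2, 0.45),
    seed=None,
):
    """Single-class genotype matrix with known redundancy structure.

    The first ``m_independent`` columns are independent HWE SNPs; each of the
    remaining ``m_redundant`` columns copies a randomly chosen independent
    column, with every entry independently resampled from that column's HWE
    distribution with probability ``noise``.  Returns ``(data, parents)``
    where ``parents[j]`` is the index of the column j was copied from
    (``parents[j] == j`` for the independent block).
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    rng = _as_rng(seed)
    m = m_independent + m_redundant
    theta = rng.uniform(*maf_range, size=m_independent)
    values = np.empty((n_samples, m), dtype=np.int8)
    values[:, :m_independent] = rng.binomial(
        2, theta, size=(n_samples, m_independent)
    )
    parents = np.arange(m)
    for j in range(m_independent, m):
        parent = int(rng.integers(m_independent))
        parents[j] = parent
        col = values[:, parent].copy()
        if noise > 0:
            flip = rng.random(n_samples) < noise
            col[flip] = rng.binomial(2, theta[parent], size=int(flip.sum()))
        values[:, j] = col
    data = GenotypeMatrix(values=values, labels=np.ones(n_samples, dtype=int))
    return data, parents


def empirical_pmf(column: np.ndarray) -> np.ndarray:
    """Observed genotype frequencies over codes {0,1,2} for one SNP column."""
    counts = np.bincount(np.asarray(column, dtype=int), minlength=3)[:3]
    return counts / counts.sum()


def hwe_gof_pvalue(column: np.ndarray, theta: float) -> float:
    """Chi-square goodness-of-fit p-value of a column against hwe_pmf(theta)."""
    counts = np.bincount(np.asarray(column, dtype=int), minlength=3)[:3]
    expected = hwe_pmf(theta) * counts.sum()
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=2))
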