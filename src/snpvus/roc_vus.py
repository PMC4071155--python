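"""ROC surfaces: operating points, AUC (D=2) and VUS (D>=3).

An operating point is the vector xi = (xi_1, ..., xi_D) of per-class
correct-classification rates obtained by shifting the classifier's pairwise
thresholds with D-1 free per-class offsets (K_1, ..., K_{D-1}), K_D = 0 --
the family swept by varying the class priors.  For D = 2 this is the usual
ROC curve and the AUC is computed by deterministic grid integration.  For
D >= 3 the volume under the ROC hypersurface (VUS) is estimated by an
alternating ant-colony / genetic search over threshold space: operating
points whose components are all positive are accumulated into a point
cloud, the cloud is closed below with base points (first component zeroed)
and the unit-simplex anchors, and the VUS is the convex-hull volume of the
closed cloud.  Iterations stop when the volume gain falls below a
tolerance.  A random classifier has VUS = 1/D!; a perfect one, VUS = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .design import GenotypeMatrix
from .pcc import GaussianApprox, orthant_probability_batch

__all__ = [
    "SearchParams",
    "OperatingPoint",
    "VUSResult",
    "GaussianXi",
    "EmpiricalXi",
    "operating_point",
    "auc",
    "vus",
    "vus_empirical",
    "hull_volume",
]


@dataclass(frozen=True)
class SearchParams:
    """Tunables of the stochastic threshold search.

    A deterministic coarse grid plus ``n_init`` random threshold vectors
    seed the first iteration; each later iteration proposes ``batch`` new
    vectors by either perturbing retained ones with Gaussian noise of scale
    ``noise`` (default 0.25 x the interquartile range of retained
    components) or by uniform crossover + mutation of retained parents.
    The search stops when the hull volume grows by less than ``tol``
    (after ``min_iter`` iterations) or at ``max_iter``.  ``n_init``,
    ``batch`` and ``min_iter`` default to None, meaning they scale with the
    threshold dimension: (512, 256, 6) for D = 3 and (4096, 2048, 12) for
    D >= 4, where covering the higher-dimensional surface needs far more
    points.
    """

    n_init: int | None = None
    batch: int | None = None
    noise: float | None = None
    crossover: float = 0.9
    mutation: float = 0.1
    tol: float = 1e-3
    min_iter: int | None = None
    max_iter: int = 200

    def resolved(self, d: int) -> "SearchParams":
        """Fill dimension-dependent defaults for a (D-1)-dim threshold space."""
        small = d <= 2
        return SearchParams(
            n_init=self.n_init if self.n_init is not None else (512 if small else 4096),
            batch=self.batch if self.batch is not None else (256 if small else 2048),
            noise=self.noise,
            crossover=self.crossover,
            mutation=self.mutation,
            tol=self.tol,
            min_iter=self.min_iter if self.min_iter is not None else (6 if small else 12),
            max_iter=self.max_iter,
        )


@dataclass(frozen=True)
class OperatingPoint:
    """One point of the ROC hypersurface and the thresholds producing it."""

    xi: np.ndarray
    kvec: np.ndarray

    @property
    def contributes(self) -> bool:
        return bool((self.xi > 0).all())


@dataclass
class VUSResult:
    volume: float
    points: np.ndarray
    iterations: int
    converged: bool
    history: list = field(default_factory=list)


def _full_offsets(kvecs: np.ndarray) -> np.ndarray:
    """Per-class threshold offsets (-K_1, ..., -K_{D-1}, 0) from kvecs."""
    kvecs = np.atleast_2d(kvecs)
    return np.hstack([-kvecs, np.zeros((kvecs.shape[0], 1))])


class GaussianXi:
    """xi(kvec) evaluator from per-class Gaussian score approximations."""

    def __init__(self, approxes: list[GaussianApprox]):
        self.approxes = list(approxes)
        self.D = len(approxes)
        if self.D < 2:
            raise ValueError("need at least 2 classes")
        half = 0.0
        for a in self.approxes:
            sd = np.sqrt(np.clip(np.diag(a.sigma), 0, None))
            half = max(half, float(np.max(np.abs(a.kvec - a.mu) + 8.0 * sd)))
        self.box_halfwidth = max(half, 1.0)

    def __call__(self, kvecs: np.ndarray) -> np.ndarray:
        offs = _full_offsets(kvecs)
        xi = np.empty((offs.shape[0], self.D))
        for k, a in enumerate(self.approxes):
            shift = offs[:, list(a.others)] - offs[:, [k]]
            xi[:, k] = orthant_probability_batch(a.mu, a.sigma, a.kvec + shift)
        return xi


class EmpiricalXi:
    """xi(kvec) evaluator from correct rates on a labelled test set."""

    def __init__(self, classifier, test_data: GenotypeMatrix):
        self.classes = np.asarray(classifier.classes_)
        self.D = len(self.classes)
        present = np.unique(test_data.labels)
        if not np.isin(self.classes, present).all():
            raise ValueError("test data must contain samples from every class")
        self.margins = classifier.pairwise_margins(test_data.values)
        self.class_rows = [
            np.flatnonzero(test_data.labels == c) for c in self.classes
        ]
        span = float(np.nanmax(np.abs(self.margins))) if self.margins.size else 1.0
        self.box_halfwidth = max(1.25 * span, 1.0)

    def __call__(self, kvecs: np.ndarray) -> np.ndarray:
        offs = _full_offsets(kvecs)
        D = self.D
        diag = np.arange(D)
        xi = np.empty((offs.shape[0], D))
        for lo in range(0, offs.shape[0], 64):  # chunked to bound memory
            off = offs[lo : lo + 64]
            shift = off[:, None, None, :] - off[:, None, :, None]
            m = self.margins[None, :, :, :] - shift
            m[:, :, diag, diag] = np.inf
            assigned = m.min(axis=3).argmax(axis=2)  # (chunk, samples)
            for k, rows in enumerate(self.class_rows):
                xi[lo : lo + 64, k] = (assigned[:, rows] == k).mean(axis=1)
        return xi


def operating_point(kvec, evaluator) -> OperatingPoint:
    """Evaluate the per-class correct rates at one threshold vector."""
    kvec = np.atleast_1d(np.asarray(kvec, dtype=float))
    xi = evaluator(kvec[None, :])[0]
    return OperatingPoint(xi=xi, kvec=kvec)


def _closed_cloud(points: np.ndarray, D: int) -> np.ndarray:
    """Close an operating-point cloud below by its dominated boxes.

    Any rate vector dominated componentwise by an achievable operating
    point is itself achievable (degrade each class's assignments at
    random), so the region the VUS integrates is the union of the boxes
    [0, xi] over the cloud.  Its convex hull is the hull of every point
    with each coordinate subset zeroed -- the corners of those boxes --
    which includes the base points with first component set to zero, the
    origin and (in the limit of extreme thresholds) the D unit vectors;
    the unit vectors are appended explicitly so the hull is bounded below
    by the unit simplex from the first iteration on.
    """
    anchors = np.vstack([np.zeros((1, D)), np.eye(D)])
    if len(points) == 0:
        return anchors
    masks = np.array(
        [[(c >> i) & 1 for i in range(D)] for c in range(2**D)], dtype=float
    )
    corners = points[:, None, :] * masks[None, :, :]
    return np.vstack([corners.reshape(-1, D), anchors])


def _hull(points: np.ndarray) -> ConvexHull:
    try:
        return ConvexHull(points)
    except QhullError:
        # wide-merge precision failures on heavily coplanar 4-d clouds:
        # joggle the input (volume perturbation ~1e-10)
        return ConvexHull(points, qhull_options="QJ")


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume of the operating-point cloud closed below."""
    points = np.atleast_2d(points)
    D = points.shape[1]
    return float(_hull(_closed_cloud(points, D)).volume)


def _search(evaluator, params: SearchParams, seed) -> VUSResult:
    rng = np.random.default_rng(seed)
    D = evaluator.D
    d = D - 1
    params = params.resolved(d)
    B = evaluator.box_halfwidth
    # deterministic coverage first: a coarse tensor grid over the threshold
    # box (including its corners), then uniform random fill
    levels = {1: 65, 2: 21, 3: 11}.get(d, 7)
    axis = np.linspace(-B, B, levels)
    grid = np.stack(np.meshgrid(*([axis] * d), indexing="ij"), axis=-1).reshape(-1, d)
    cand = np.vstack([grid, rng.uniform(-B, B, size=(params.n_init, d))])
    cloud = np.empty((0, D))
    vertices = np.empty((0, D))  # current hull vertex set of the closed cloud
    kept = np.empty((0, d))
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        xi = evaluator(cand)
        good = (xi > 0).all(axis=1)
        cloud = np.vstack([cloud, xi[good]])
        kept = np.vstack([kept, cand[good]])
        hull = _hull(np.vstack([vertices, _closed_cloud(xi[good], D)]))
        vertices = hull.points[hull.vertices]
        vol = float(hull.volume)
        history.append(vol)
        if len(history) > 1 and it >= params.min_iter:
            if history[-1] - history[-2] < params.tol:
                converged = True
                break
        if len(kept) == 0:
            cand = rng.uniform(-B, B, size=(params.batch, d))
        elif it % 2 == 1:  # ant-colony step: jitter retained thresholds
            parents = kept[rng.integers(len(kept), size=params.batch)]
            if params.noise is not None:
                scale = params.noise
            else:
                q75, q25 = np.percentile(kept, [75, 25], axis=0)
                iqr = np.maximum(q75 - q25, 1e-3 * B)
                scale = 0.25 * iqr
            cand = parents + rng.normal(scale=scale, size=parents.shape)
        else:  # genetic step: uniform crossover + mutation
            pa = kept[rng.integers(len(kept), size=params.batch)]
            pb = kept[rng.integers(len(kept), size=params.batch)]
            mask = rng.random(pa.shape) < 0.5
            child = np.where(mask, pa, pb)
            cross = rng.random(params.batch) < params.crossover
            cand = np.where(cross[:, None], child, pa)
            mut = rng.random(cand.shape) < params.mutation
            cand[mut] = rng.uniform(-B, B, size=int(mut.sum()))
        cand = np.clip(cand, -2 * B, 2 * B)
    if cloud.shape[0] + D + 1 < D + 1:  # pragma: no cover - anchors prevent this
        raise RuntimeError("threshold search found no contributing points")
    return VUSResult(
        volume=history[-1],
        points=cloud,
        iterations=it,
        converged=converged,
        history=history,
    )


def vus(evaluator, search_params: SearchParams | None = None, seed=None) -> VUSResult:
    """Volume under the ROC hypersurface by stochastic threshold search.

    ``evaluator`` maps an (M, D-1) array of threshold vectors to (M, D)
    per-class correct rates (``GaussianXi`` for the analytic variants,
    ``EmpiricalXi`` for Monte-Carlo test-set rates).  Identical seeds give
    identical results; the volume history is nondecreasing because the
    operating-point cloud is cumulative.
    """
    if evaluator.D < 3:
        raise ValueError("VUS requires D >= 3; use auc() for two classes")
    return _search(evaluator, search_params or SearchParams(), seed)


def vus_empirical(
    classifier,
    test_data: GenotypeMatrix,
    search_params: SearchParams | None = None,
    seed=None,
) -> VUSResult:
    """Monte-Carlo VUS: the same search with empirical test-set rates."""
    return vus(EmpiricalXi(classifier, test_data), search_params, seed)


def auc(evaluator, n_grid: int = 1024) -> float:
    """Area under the ROC curve (D = 2) by deterministic grid integration.

    Sweeps the scalar threshold offset over a grid spanning +-8 sd of both
    class score distributions and integrates xi_2 against xi_1 by the
    trapezoid rule, with the (1, 0) and (0, 1) endpoints appended.
    """
    if evaluator.D != 2:
        raise ValueError("auc is defined for exactly 2 classes")
    n_grid = max(int(n_grid), 512)
    B = evaluator.box_halfwidth
    grid = np.linspace(-B, B, n_grid)[:, None]
    xi = evaluator(grid)
    xi1 = np.concatenate([[1.0], xi[:, 0], [0.0]])
    xi2 = np.concatenate([[0.0], xi[:, 1], [1.0]])
    return float(abs(np.trapezoid(xi2, xi1)))
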