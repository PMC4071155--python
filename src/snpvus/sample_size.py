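"""Sample-size determination from the VUS (or AUC) learning curve.

The smallest per-class sample size n is sought such that the performance
lost to parameter estimation, VUS(infinity) - VUS(n), falls below a
user-chosen threshold gamma, i.e. the smallest integer root of

    f(n) = VUS(infinity) - VUS(n) - gamma < 0,

found by integer bisection on a bracket [n_S, n_L] with f(n_S) > 0 and
f(n_L) < 0.  VUS(n) is evaluated through the estimation-adjusted Gaussian
approximation, and all VUS searches share one random seed (common random
numbers) so that Monte-Carlo noise in the threshold search does not break
the sign logic of the bisection.  For D = 2 the AUC gap is used instead
(deterministic grid integration, no search noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import MAFProfile, StudyDesign
from .pcc import class_approxes
from .roc_vus import GaussianXi, SearchParams, auc, vus

__all__ = ["SampleSizeSearch", "vus_gap", "find_sample_size", "learning_curve"]

_MAX_N = 400_000


def _default_gap_params(D: int) -> SearchParams:
    """Search effort for gap evaluations.

    The bisection consumes *differences* of volumes under common random
    numbers, which are insensitive to the hull's absolute coverage deficit
    (effort-doubling changes the D=4 gap by <0.002), so 4-d gap searches
    default to roughly half the effort of an absolute-VUS search.
    """
    if D <= 3:
        return SearchParams()
    return SearchParams(n_init=2048, batch=1024, min_iter=8)


@dataclass
class SampleSizeSearch:
    """Outcome of the integer bisection for one gamma."""

    gamma: float
    n_S: int
    n_L: int
    result_n: int
    total_n: int
    vus_infty: float
    f_evals: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)


def _volume(profile: MAFProfile, design: StudyDesign, variant, params, seed) -> float:
    approxes = class_approxes(profile, design, variant=variant)
    ev = GaussianXi(approxes)
    if profile.D == 2:
        return auc(ev)
    return vus(ev, params, seed=seed).volume


def vus_gap(
    profile: MAFProfile,
    n: int,
    gamma: float,
    alpha: float = 0.1,
    rho: float = 1.0,
    search_params: SearchParams | None = None,
    seed=None,
    vus_infty: float | None = None,
) -> float:
    """f(n) = VUS(infinity) - VUS(n) - gamma (AUC gap when D = 2).

    The same ``seed`` should be passed for every n (common random numbers);
    ``vus_infty`` may be supplied to avoid recomputing the n-free term.
    """
    if search_params is None:
        search_params = _default_gap_params(profile.D)
    design = StudyDesign(D=profile.D, m=profile.m, n_per_class=int(n), rho=rho, alpha=alpha)
    if vus_infty is None:
        vus_infty = _volume(profile, design, "infty", search_params, seed)
    return vus_infty - _volume(profile, design, "n", search_params, seed) - gamma


def find_sample_size(
    profile: MAFProfile,
    gamma: float,
    alpha: float = 0.1,
    rho: float = 1.0,
    bracket: tuple = (10, 5000),
    search_params: SearchParams | None = None,
    seed=None,
    gap_fn=None,
    gap_cache: dict | None = None,
    verify: bool = True,
) -> SampleSizeSearch:
    """Smallest per-class n with VUS(infinity) - VUS(n) < gamma.

    Bisects on integers: while n_L - n_S > 1 the midpoint replaces
    whichever end keeps f(n_S) > 0 and f(n_L) < 0; the answer is n = n_L.
    The initial bracket auto-expands geometrically (x4) when it does not
    straddle the root.  Unless disabled, the returned n is re-verified at
    n and n-1 with a tightened search (3x initial points, tolerance
    0.0005) and locally adjusted if the refined sign flips.

    ``gap_fn`` (n -> VUS(infinity) - VUS(n)) may be injected for testing or
    cache sharing; ``gap_cache`` maps n to already-computed gaps.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    params = (search_params or _default_gap_params(profile.D)).resolved(profile.D - 1)
    cache = gap_cache if gap_cache is not None else {}
    vinf_holder = {}

    def default_gap(n: int, refined: bool = False) -> float:
        p = params
        if refined:
            # tighter stopping; extra points only where they are cheap
            grow = 3 if profile.D <= 3 else 1
            p = replace(params, n_init=grow * params.n_init, tol=5e-4)
        design = StudyDesign(D=profile.D, m=profile.m, n_per_class=n, rho=rho, alpha=alpha)
        key = "ref" if refined else "std"
        if key not in vinf_holder:
            vinf_holder[key] = _volume(profile, design, "infty", p, seed)
        return vinf_holder[key] - _volume(profile, design, "n", p, seed)

    if gap_fn is None:
        gap_fn = default_gap

    trace: list = []

    def f(n: int, refined: bool = False) -> float:
        n = int(n)
        key = (n, refined)
        if key not in cache:
            try:
                cache[key] = float(gap_fn(n, refined=refined))
            except TypeError:
                cache[key] = float(gap_fn(n))
        val = cache[key] - gamma
        trace.append((n, val))
        return val

    n_S, n_L = int(bracket[0]), int(bracket[1])
    # shrink the lower end until f(n_S) > 0 (or conclude n = 1 suffices)
    while f(n_S) <= 0 and n_S > 1:
        n_L = n_S
        n_S = max(1, n_S // 4)
    if f(n_S) <= 0:  # f(1) <= 0: a single sample per class already suffices
        return _result(gamma, n_S, 1, 1, vinf_holder, cache, trace, profile)
    while f(n_L) >= 0:
        if n_L >= _MAX_N:
            raise RuntimeError(
                f"could not bracket the root: f({n_L}) = {f(n_L):.4g} >= 0; "
                f"gamma={gamma} may be unattainably small for this design"
            )
        n_L = min(4 * n_L, _MAX_N)
    while n_L - n_S > 1:
        n_M = (n_S + n_L) // 2
        # f(n_S) > 0 is maintained, so the sign of f(n_M) decides the side
        # (robust to an exact zero at either end)
        if f(n_M) < 0:
            n_L = n_M
        else:
            n_S = n_M
    if verify:
        # the gap is Monte-Carlo noisy: re-check the root with extra effort;
        # coarse steps up if the refined sign flips, unit steps down to keep
        # the returned n minimal
        step = max(1, n_L // 50)
        ups = 0
        while f(n_L, refined=True) >= 0 and ups < 8:
            n_L += step
            ups += 1
        downs = 0
        while n_L > 1 and f(n_L - 1, refined=True) < 0 and downs < step + 8:
            n_L -= 1
            downs += 1
        n_S = n_L - 1
    return _result(gamma, n_S, n_L, n_L, vinf_holder, cache, trace, profile)


def _result(gamma, n_S, n_L, result_n, vinf_holder, cache, trace, profile):
    return SampleSizeSearch(
        gamma=gamma,
        n_S=int(n_S),
        n_L=int(n_L),
        result_n=int(result_n),
        total_n=int(profile.D * result_n),
        vus_infty=float(vinf_holder.get("std", np.nan)),
        f_evals=dict(cache),
        trace=trace,
    )


def learning_curve(
    profile: MAFProfile,
    gamma_grid,
    alpha: float = 0.1,
    rho: float = 1.0,
    bracket: tuple = (10, 5000),
    search_params: SearchParams | None = None,
    seed=None,
    verify: bool = False,
):
    """Required (per-class, total) sample size for each gamma in a grid.

    One VUS(n) evaluation cache is shared across all gamma values (the
    criterion f is just a gamma-shift of the same gap curve), so the curve
    costs little more than a single search.  Returns a list of
    ``(gamma, n_per_class, n_total)`` tuples, nonincreasing in gamma.
    """
    gammas = sorted(float(g) for g in np.atleast_1d(gamma_grid))
    if not all(0 < g < 1 for g in gammas):
        raise ValueError("all gamma values must lie in (0, 1)")
    cache: dict = {}
    rows = []
    hi = int(bracket[1])
    for g in reversed(gammas):  # large gamma first: smaller n, cheap evals
        res = find_sample_size(
            profile,
            g,
            alpha=alpha,
            rho=rho,
            bracket=(int(bracket[0]), hi),
            search_params=search_params,
            seed=seed,
            gap_cache=cache,
            verify=verify,
        )
        rows.append((g, res.result_n, res.total_n))
    return rows[::-1]
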