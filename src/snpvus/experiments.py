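"""Scripted simulation studies: classifier performance and sample sizes.

Two studies are provided over the U(0.4, 0.49)-anchored MAF-shift designs:

* ``run_table1`` -- for cells (D, h, m, n): the approximate VUS(infinity)
  of the optimal Bayes rule, the estimation-adjusted VUS(n) of the linear
  rule, and a Monte-Carlo check VUS_MC from linear classifiers fitted on
  simulated training sets and scored on independent test sets; the bias
  VUS_MC - VUS(n) measures the quality of the Gaussian approximation.
* ``run_table2`` -- for cells (D, h, m): the smallest per-class n with
  VUS(infinity) - VUS(n) < gamma, by integer bisection.

Replication defaults are reduced (5 design draws x 5 datasets) for desk
runtime; the original studies use 20 x 20.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .classifiers import build_linear
from .design import StudyDesign, simulate_genotypes, table1_design
from .pcc import class_approxes
from .roc_vus import GaussianXi, SearchParams, vus, vus_empirical
from .sample_size import find_sample_size

__all__ = ["Table1Row", "run_table1", "run_table2"]


@dataclass
class Table1Row:
    D: int
    h: float
    m: int
    n: int
    vus_infty: float
    vus_n: float
    vus_mc: float
    bias: float
    se_vus_infty: float
    se_vus_mc: float
    reps_design: int
    reps_data: int


def _seeds(seed, n):
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_table1(
    cells,
    reps_design: int = 5,
    reps_data: int = 5,
    alpha: float = 0.1,
    n_test: int = 400,
    search_params: SearchParams | None = None,
    seed=None,
) -> list[Table1Row]:
    """Approximate and Monte-Carlo VUS for each (D, h, m, n) cell.

    VUS(infinity) and VUS(n) are averaged over ``reps_design`` independent
    MAF-profile draws; VUS_MC additionally averages, per draw,
    ``reps_data`` fitted linear classifiers each scored on a fresh test set
    of ``n_test`` samples per class.  Standard errors across design draws
    are attached.
    """
    params = search_params or SearchParams()
    rows = []
    for ci, (D, h, m, n) in enumerate(cells):
        cell_seeds = _seeds(None if seed is None else seed + 7919 * ci, reps_design)
        v_inf, v_n, v_mc = [], [], []
        for r, s in enumerate(cell_seeds):
            rng = np.random.default_rng(s)
            profile = table1_design(D, h, m, seed=rng)
            design = StudyDesign(D=D, m=m, n_per_class=n, alpha=alpha)
            v_inf.append(
                vus(GaussianXi(class_approxes(profile, design, "infty")), params, seed=s).volume
            )
            v_n.append(
                vus(GaussianXi(class_approxes(profile, design, "n")), params, seed=s).volume
            )
            mc = []
            for _ in range(reps_data):
                train = simulate_genotypes(profile, n, seed=rng)
                clf = build_linear(train, alpha=alpha)
                test = simulate_genotypes(profile, n_test, seed=rng)
                mc.append(vus_empirical(clf, test, params, seed=s).volume)
            v_mc.append(float(np.mean(mc)))
        v_inf, v_n, v_mc = map(np.asarray, (v_inf, v_n, v_mc))
        rows.append(
            Table1Row(
                D=D, h=h, m=m, n=n,
                vus_infty=float(v_inf.mean()),
                vus_n=float(v_n.mean()),
                vus_mc=float(v_mc.mean()),
                bias=float(v_mc.mean() - v_n.mean()),
                se_vus_infty=float(v_inf.std(ddof=1) / np.sqrt(len(v_inf)))
                if len(v_inf) > 1 else 0.0,
                se_vus_mc=float(v_mc.std(ddof=1) / np.sqrt(len(v_mc)))
                if len(v_mc) > 1 else 0.0,
                reps_design=reps_design,
                reps_data=reps_data,
            )
        )
    return rows


def run_table2(
    cells,
    gamma: float = 0.01,
    alpha: float = 0.1,
    bracket: tuple = (10, 5000),
    search_params: SearchParams | None = None,
    seed=None,
) -> pd.DataFrame:
    """Per-class and total sample size for each (D, h, m) cell at gamma."""
    records = []
    for ci, (D, h, m) in enumerate(cells):
        s = None if seed is None else seed + 104729 * ci
        profile = table1_design(D, h, m, seed=s)
        res = find_sample_size(
            profile, gamma, alpha=alpha, bracket=bracket,
            search_params=search_params, seed=s,
        )
        records.append(
            {
                "D": D, "h": h, "m": m, "gamma": gamma,
                "n_per_class": res.result_n, "n_total": res.total_n,
                "vus_infty": res.vus_infty,
            }
        )
    return pd.DataFrame.from_records(records)


def table1_frame(rows: list[Table1Row]) -> pd.DataFrame:
    return pd.DataFrame.from_records([asdict(r) for r in rows])
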