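"""Canned parameter-recovery experiments.

These are the reproducible simulation studies the package uses to
demonstrate that the REML machinery recovers known truth: data are
simulated under the repeatability animal model at a stated design, fitted,
and the estimated ratios compared with the generating values.  Both the
test suite and the results-reproduction script run them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genparams as gp
from . import reml as rm
from .pedigree import build_nrm_inverse
from .simulate import MPE1_TRUE_COMPONENTS, simulate_single_trait, simulate_two_traits

__all__ = ["univariate_recovery", "bivariate_recovery"]

#: design of the headline recovery experiment: paternal half-sib families,
#: two lactation records per cow, intercept-only fixed structure
DEFAULT_DESIGN = dict(n_sires=200, daughters_per_sire=10, records_per_cow=2)


def univariate_recovery(
    seeds,
    components=MPE1_TRUE_COMPONENTS,
    mean: float = 30934.0,
    n_sires: int = 200,
    daughters_per_sire: int = 10,
    records_per_cow: int = 2,
) -> pd.DataFrame:
    """Simulate-and-refit heritability/repeatability recovery.

    For each seed, a half-sib herd is simulated with the given true
    (s2a, s2pe, s2e), fitted by univariate REML with an intercept-only
    fixed structure, and the estimated components and ratios recorded.
    """
    s2a, s2pe, s2e = components
    rows = []
    spec = rm.ModelSpec(trait="y", fixed_factors=(), covariates=())
    for seed in seeds:
        ped, rec = simulate_single_trait(
            n_sires, daughters_per_sire, records_per_cow,
            s2a, s2pe, s2e, mean=mean, seed=int(seed),
        )
        Ainv = build_nrm_inverse(ped)
        dm = rm.build_design(rec, ped, spec)
        vc = rm.reml_univariate(dm, Ainv, rec["y"], trait="y")
        rows.append(
            {
                "seed": int(seed),
                "sigma2_a": vc.sigma2_a,
                "sigma2_pe": vc.sigma2_pe,
                "sigma2_e": vc.sigma2_e,
                "h2": gp.heritability(vc),
                "repeatability": gp.repeatability(vc),
                "logL": vc.logL,
                "converged": vc.converged,
                "iterations": vc.iterations,
            }
        )
    return pd.DataFrame(rows)


def bivariate_recovery(
    seeds,
    G_a,
    G_pe,
    R0,
    n_sires: int = 200,
    daughters_per_sire: int = 10,
    records_per_cow: int = 2,
) -> pd.DataFrame:
    """Simulate-and-refit genetic-correlation recovery for two traits."""
    rows = []
    spec = rm.ModelSpec(fixed_factors=(), covariates=())
    for seed in seeds:
        ped, rec = simulate_two_traits(
            n_sires, daughters_per_sire, records_per_cow,
            G_a, G_pe, R0, seed=int(seed),
        )
        Ainv = build_nrm_inverse(ped)
        dm = rm.build_design(rec, ped, spec)
        fit = rm.reml_bivariate(
            dm, Ainv, rec["y1"], rec["y2"], traits=("y1", "y2")
        )
        rows.append(
            {
                "seed": int(seed),
                "rg": fit.rg(),
                "rp": fit.rp(),
                "Ga11": fit.G_a[0, 0],
                "Ga12": fit.G_a[0, 1],
                "Ga22": fit.G_a[1, 1],
                "logL": fit.logL,
                "converged": fit.converged,
                "iterations": fit.iterations,
            }
        )
    return pd.DataFrame(rows)
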