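"""Shared fixtures: reference pedigrees, half-sib datasets, heavy fits.

Expensive simulation-and-refit experiments are session-scoped so that the
acceptance-style checks and the structural-invariant checks share one
computation.
"""

import numpy as np
import pytest

from methaherd import reml as rm
from methaherd import simulate as sim
from methaherd.experiments import univariate_recovery
from methaherd.pedigree import Pedigree, build_nrm_inverse


@pytest.fixture(scope="session")
def trio_ped():
    return Pedigree.from_parent_map(
        {"A": (None, None), "B": (None, None), "C": ("A", "B")}
    )


@pytest.fixture(scope="session")
def fullsib_ped():
    """Full-sib mating: E is inbred (F = 0.25)."""
    return Pedigree.from_parent_map(
        {
            "A": (None, None),
            "B": (None, None),
            "C": ("A", "B"),
            "D": ("A", "B"),
            "E": ("C", "D"),
        }
    )


@pytest.fixture(scope="session")
def medium_pedigree():
    """Multi-generation pedigree (~400 animals) with founder dams."""
    cfg = sim.SimulationConfig(
        seed=5, n_sires=15, daughters_per_sire=8, n_generations=2,
        use_founder_dams=True,
    )
    return sim.simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def halfsib_small():
    """50 sires x 4 daughters x 2 records with known truth (2, 1, 3).

    Returns (pedigree, records, design, A-inverse); intercept-only fixed
    structure.  Reused by invariance and bivariate boundary tests.
    """
    ped, rec = sim.simulate_single_trait(50, 4, 2, 2.0, 1.0, 3.0, seed=7)
    Ainv = build_nrm_inverse(ped)
    dm = rm.build_design(rec, ped, rm.ModelSpec(fixed_factors=(), covariates=()))
    return ped, rec, dm, Ainv


@pytest.fixture(scope="session")
def mpe1_recovery():
    """10-seed heritability/repeatability recovery at the published truth.

    200 sires x 10 daughters, 2 records/cow, true components
    (6,771,940; 3,371,540; 12,418,000); intercept-only fixed structure.
    """
    return univariate_recovery(range(1, 11))


@pytest.fixture(scope="session")
def null_bivariate_fits():
    """Bivariate fits of independently simulated traits (true rg = 0).

    Five seeds at 200 sires x 10 daughters x 2 records; also returns the
    univariate fits of each trait for marginal-agreement checks.
    """
    import warnings

    from methaherd.pedigree import build_nrm_inverse as bni

    Ga = np.diag([4.0, 9.0])
    Gpe = np.diag([2.0, 4.0])
    R0 = np.diag([6.0, 12.0])
    out = []
    spec = rm.ModelSpec(fixed_factors=(), covariates=())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 6):
            ped, rec = sim.simulate_two_traits(200, 10, 2, Ga, Gpe, R0, seed=seed)
            Ainv = bni(ped)
            dm = rm.build_design(rec, ped, spec)
            biv = rm.reml_bivariate(dm, Ainv, rec["y1"], rec["y2"], traits=("y1", "y2"))
            uni = (
                rm.reml_univariate(dm, Ainv, rec["y1"], trait="y1"),
                rm.reml_univariate(dm, Ainv, rec["y2"], trait="y2"),
            )
            out.append((biv, uni))
    return out
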