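"""Synthetic dairy herds with known genetic architecture.

The real milk-recording data behind this kind of analysis (tens of
thousands of Holstein-Friesian lactations) are not publicly deposited, so
every stage of the pipeline is exercised on simulated herds whose true
variance components are known.  The generator runs the repeatability animal
model forward:

1. a pedigree of founder sires (optionally founder dams) and one or more
   generations of daughters by random mating;
2. breeding values by gene dropping: founders ~ N(0, G); offspring are the
   parent average plus a Mendelian-sampling deviation with variance
   ``d_i * G`` where ``d_i`` accounts for known parents and their
   inbreeding — so effect covariances converge to ``A (x) G``;
3. lactation records ``y = mean + fixed effects + a + pe + e`` for four base
   milk traits (milk, fat, protein, lactose yields, kg/lactation) drawn
   jointly with configurable genetic and environmental correlations; dry
   matter is fat+protein+lactose plus a small positive "other solids"
   margin, which keeps the composition constraint satisfied by
   construction;
4. methane phenotypes computed deterministically from the milk traits by
   the prediction equations (the phenotype is indirect by definition); an
   optional noise term (default off) lets tests explore genetic
   correlations below one.

Defaults reproduce the published study scale: trait means/SDs as recorded
for the ~17,468-cow population, 28 herds, four calving seasons, parities
1-6 with a truncated-geometric record count averaging ~2.18 records/cow,
and milk variance components chosen so the milk-yield-based methane
phenotype has the published additive/permanent/residual components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import methane as mt
from .pedigree import Pedigree, inbreeding

__all__ = [
    "SimulationConfig",
    "SyntheticHerd",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_records",
    "simulate_single_trait",
    "simulate_two_traits",
    "small_preset",
    "full_preset",
    "truncated_geometric_p",
    "TABLE1_MEANS",
    "TABLE1_SDS",
    "MPE1_TRUE_COMPONENTS",
]

#: published summary scale of the study population (kg/lactation)
TABLE1_MEANS = {"milk": 11221.0, "fat": 428.0, "protein": 375.0, "lactose": 546.0}
TABLE1_SDS = {"milk": 2353.0, "fat": 92.0, "protein": 74.0, "lactose": 114.0}

#: published additive / permanent-environment / residual variances of the
#: milk-yield-based methane phenotype (g/lactation)^2
MPE1_TRUE_COMPONENTS = (6_771_940.0, 3_371_540.0, 12_418_000.0)

_BASE_TRAITS = ("milk", "fat", "protein", "lactose")

# genetic and environmental correlations among yield traits; field-typical
# values for Holstein yield traits (yields, not percentages, are highly
# positively correlated)
_GENETIC_CORR = np.array(
    [
        [1.00, 0.60, 0.90, 0.95],
        [0.60, 1.00, 0.65, 0.55],
        [0.90, 0.65, 1.00, 0.90],
        [0.95, 0.55, 0.90, 1.00],
    ]
)
_ENV_CORR = np.array(
    [
        [1.00, 0.70, 0.92, 0.96],
        [0.70, 1.00, 0.75, 0.65],
        [0.92, 0.75, 1.00, 0.92],
        [0.96, 0.65, 0.92, 1.00],
    ]
)


def truncated_geometric_p(mean: float, kmax: int = 6) -> float:
    """Success parameter of a geometric truncated to 1..kmax with given mean."""
    if not 1.0 < mean < kmax:
        raise ValueError(f"mean must lie in (1, {kmax})")

    def m(p):
        k = np.arange(1, kmax + 1)
        w = p * (1 - p) ** (k - 1)
        w /= w.sum()
        return float(k @ w) - mean

    return brentq(m, 1e-9, 1 - 1e-9)


def _component_fractions():
    """(a, pe, e) fractions implied by the published methane components."""
    a, pe, e = MPE1_TRUE_COMPONENTS
    tot = a + pe + e
    return a / tot, pe / tot, e / tot


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-herd generator.

    The defaults are the study conditions; ``small_preset`` /
    ``full_preset`` change only the population size.  Variances are on the
    kg/lactation scale of each trait.
    """

    seed: int = 1
    n_sires: int = 200
    daughters_per_sire: int = 10
    n_generations: int = 1
    use_founder_dams: bool = False
    parity_max: int = 6
    mean_records_per_cow: float = 38011.0 / 17468.0  # ~2.176
    records_fixed: int | None = None  # exact records/cow, overrides the mean
    n_herds: int = 28
    n_years: int = 12
    n_seasons: int = 4
    lactation_length_range: tuple[int, int] = (200, 400)
    trait_means: dict = field(default_factory=lambda: dict(TABLE1_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(TABLE1_SDS))
    # fraction of each trait's published SD that is modelled by the random
    # effects; the remainder is headroom for fixed effects.  The default
    # makes the milk components exactly the published methane components
    # rescaled by the squared milk slope of the prediction equation.
    random_sd_fraction: float = float(
        np.sqrt(sum(MPE1_TRUE_COMPONENTS)) / 2.73 / TABLE1_SDS["milk"]
    )
    # per-factor SD of level effects, as a fraction of the trait mean
    fixed_effect_sd_fraction: float = 0.015
    # lactation-length slope: slope = fraction * mean / 310 (kg per day)
    lactation_slope_fraction: float = 0.05
    genetic_corr: np.ndarray = field(default_factory=lambda: _GENETIC_CORR.copy())
    env_corr: np.ndarray = field(default_factory=lambda: _ENV_CORR.copy())
    dry_matter_margin_mean: float = 82.0  # kg of non-fat/protein/lactose solids
    dry_matter_margin_sd: float = 15.0
    methane_noise_sd: float = 0.0  # optional iid noise on each MPE (g)

    def __post_init__(self) -> None:
        for M in (np.asarray(self.genetic_corr), np.asarray(self.env_corr)):
            if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 1.0):
                raise ValueError("correlation matrices must be symmetric, unit diagonal")
            if np.linalg.eigvalsh(M)[0] < -1e-9:
                raise ValueError("correlation matrix is not positive semidefinite")
        if self.n_sires < 1 or self.daughters_per_sire < 1 or self.n_generations < 1:
            raise ValueError("population counts must be >= 1")

    # -- derived covariance structure --------------------------------------
    def component_variances(self) -> dict[str, tuple[float, float, float]]:
        """True (s2a, s2pe, s2e) per base trait."""
        fa, fpe, fe = _component_fractions()
        out = {}
        for t in _BASE_TRAITS:
            v = (self.random_sd_fraction * self.trait_sds[t]) ** 2
            out[t] = (fa * v, fpe * v, fe * v)
        return out

    def covariance_blocks(self):
        """(G_a, G_pe, G_e) 4x4 blocks over (milk, fat, protein, lactose)."""
        comp = self.component_variances()
        sd_a = np.array([np.sqrt(comp[t][0]) for t in _BASE_TRAITS])
        sd_pe = np.array([np.sqrt(comp[t][1]) for t in _BASE_TRAITS])
        sd_e = np.array([np.sqrt(comp[t][2]) for t in _BASE_TRAITS])
        Ga = np.asarray(self.genetic_corr) * np.outer(sd_a, sd_a)
        Gpe = np.asarray(self.env_corr) * np.outer(sd_pe, sd_pe)
        Ge = np.asarray(self.env_corr) * np.outer(sd_e, sd_e)
        return Ga, Gpe, Ge

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genetic_corr"] = np.asarray(self.genetic_corr).tolist()
        d["env_corr"] = np.asarray(self.env_corr).tolist()
        d["lactation_length_range"] = list(self.lactation_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("genetic_corr", "env_corr"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        if "lactation_length_range" in d:
            d["lactation_length_range"] = tuple(d["lactation_length_range"])
        return cls(**d)


@dataclass
class SyntheticHerd:
    """A simulated population: pedigree, records, and the true effects."""

    pedigree: Pedigree
    records: pd.DataFrame
    true_breeding_values: pd.DataFrame  # per animal, base traits
    true_permanent_env: pd.DataFrame  # per cow with records, base traits
    config: SimulationConfig

    def write(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(out / "pedigree.csv")
        self.records.to_csv(out / "phenotypes.csv", index=False)
        self.true_breeding_values.to_csv(out / "true_breeding_values.csv", index=False)
        self.true_permanent_env.to_csv(out / "true_permanent_env.csv", index=False)
        comp = self.config.component_variances()
        rows = [
            {"trait": t, "sigma2_a": a, "sigma2_pe": pe, "sigma2_e": e}
            for t, (a, pe, e) in comp.items()
        ]
        pd.DataFrame(rows).to_csv(out / "true_parameters.csv", index=False)


# ---------------------------------------------------------------------------
# pedigree and effects


def simulate_pedigree(cfg: SimulationConfig, rng=None) -> Pedigree:
    """Founder sires (and optionally dams), then generations of daughters.

    Each generation, every sire is mated to randomly chosen dams (founder
    dams for generation 1 when enabled, otherwise the previous generation's
    daughters; unknown dams when no pool exists).  Sires of later
    generations are fresh unrelated founders, which keeps matings
    selfing-free by construction.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    parents: dict[str, tuple[str | None, str | None]] = {}
    dam_pool: list[str] = []
    if cfg.use_founder_dams:
        n_dams = cfg.n_sires * cfg.daughters_per_sire
        dam_pool = [f"D0_{i}" for i in range(n_dams)]
        for d in dam_pool:
            parents[d] = (None, None)
    for g in range(1, cfg.n_generations + 1):
        sires = [f"S{g}_{j}" for j in range(cfg.n_sires)]
        for s in sires:
            parents[s] = (None, None)
        daughters = []
        for j, s in enumerate(sires):
            for i in range(cfg.daughters_per_sire):
                cow = f"C{g}_{j}_{i}"
                dam = rng.choice(dam_pool) if dam_pool else None
                parents[cow] = (s, dam)
                daughters.append(cow)
        dam_pool = daughters
    return Pedigree.from_parent_map(parents)


def simulate_breeding_values(ped: Pedigree, G, rng=None, seed=None) -> np.ndarray:
    """Gene-drop multivariate breeding values down a pedigree.

    Founders ~ N(0, G); an offspring is the mean of its known parents'
    values plus a Mendelian-sampling deviation ~ N(0, d_i G), with
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` for two known parents (1 for none,
    ``0.75 - 0.25 F_p`` for one) so that Cov(vec of effects) = A (x) G.
    Returns an (n_animals, n_traits) array in pedigree order.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    G = np.atleast_2d(np.asarray(G, dtype=float))
    T = G.shape[0]
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    if w[0] < -1e-8 * max(w[-1], 1.0):
        raise ValueError("genetic covariance matrix must be PSD")
    Lc = V * np.sqrt(np.maximum(w, 0.0))
    _, d = inbreeding(ped)
    n = len(ped)
    u = np.zeros((n, T))
    z = rng.standard_normal((n, T))
    for i in range(n):
        mean = np.zeros(T)
        s, dm = ped.sire[i], ped.dam[i]
        if s >= 0:
            mean += 0.5 * u[s]
        if dm >= 0:
            mean += 0.5 * u[dm]
        u[i] = mean + np.sqrt(d[i]) * (Lc @ z[i])
    return u


# ---------------------------------------------------------------------------
# records


def _record_counts(cfg: SimulationConfig, n_cows: int, rng) -> np.ndarray:
    if cfg.records_fixed is not None:
        return np.full(n_cows, int(cfg.records_fixed))
    p = truncated_geometric_p(cfg.mean_records_per_cow, cfg.parity_max)
    k = np.arange(1, cfg.parity_max + 1)
    w = p * (1 - p) ** (k - 1)
    w /= w.sum()
    return rng.choice(k, size=n_cows, p=w)


def simulate_records(ped: Pedigree, cfg: SimulationConfig, rng=None) -> SyntheticHerd:
    """Generate the lactation phenotype table for all non-founder females."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    Ga, Gpe, Ge = cfg.covariance_blocks()
    T = len(_BASE_TRAITS)
    means = np.array([cfg.trait_means[t] for t in _BASE_TRAITS])

    bv = simulate_breeding_values(ped, Ga, rng=rng)
    cows = [a for a in ped.ids if a.startswith("C")]
    if not cows:
        raise ValueError("pedigree contains no record-bearing cows")
    cow_rows = np.array([ped.index(c) for c in cows])
    n_cows = len(cows)
    pe = rng.multivariate_normal(np.zeros(T), Gpe, size=n_cows, method="eigh")

    counts = _record_counts(cfg, n_cows, rng)
    n_rec = int(counts.sum())

    herd_of_cow = rng.integers(1, cfg.n_herds + 1, size=n_cows)
    cow_idx = np.repeat(np.arange(n_cows), counts)
    parity = np.concatenate([np.arange(1, k + 1) for k in counts])
    year = rng.integers(1, cfg.n_years + 1, size=n_rec)
    season = rng.integers(1, cfg.n_seasons + 1, size=n_rec)
    lo, hi = cfg.lactation_length_range
    ll = rng.integers(lo, hi + 1, size=n_rec)

    # one effect value per factor level and trait
    fe_sd = cfg.fixed_effect_sd_fraction * means
    eff = {
        "herd": rng.normal(0.0, fe_sd, size=(cfg.n_herds + 1, T)),
        "year": rng.normal(0.0, fe_sd, size=(cfg.n_years + 1, T)),
        "season": rng.normal(0.0, fe_sd, size=(cfg.n_seasons + 1, T)),
        "parity": rng.normal(0.0, fe_sd, size=(cfg.parity_max + 1, T)),
    }
    slope = cfg.lactation_slope_fraction * means / 310.0

    e = rng.multivariate_normal(np.zeros(T), Ge, size=n_rec, method="eigh")
    y = (
        means[None, :]
        + eff["herd"][herd_of_cow[cow_idx]]
        + eff["year"][year]
        + eff["season"][season]
        + eff["parity"][parity]
        + slope[None, :] * (ll - 310.0)[:, None]
        + bv[cow_rows][cow_idx]
        + pe[cow_idx]
        + e
    )
    y = np.maximum(y, 1.0)  # yields are physical quantities; clip is ~never hit

    margin = np.maximum(
        rng.normal(cfg.dry_matter_margin_mean, cfg.dry_matter_margin_sd, size=n_rec),
        1.0,
    )
    rec = pd.DataFrame(
        {
            "cow": np.asarray(cows, dtype=object)[cow_idx],
            "parity": parity,
            "herd": herd_of_cow[cow_idx],
            "year": year,
            "season": season,
            "lactation_length": ll,
            "milk": y[:, 0],
            "fat": y[:, 1],
            "protein": y[:, 2],
            "lactose": y[:, 3],
        }
    )
    rec["dry_matter"] = rec["fat"] + rec["protein"] + rec["lactose"] + margin
    rec = mt.add_methane_columns(rec)
    if cfg.methane_noise_sd > 0:
        for col in mt.METHANE_TRAITS:
            rec[col] = rec[col] + rng.normal(0.0, cfg.methane_noise_sd, size=n_rec)

    bv_df = pd.DataFrame(bv, columns=list(_BASE_TRAITS))
    bv_df.insert(0, "animal", ped.ids)
    pe_df = pd.DataFrame(pe, columns=list(_BASE_TRAITS))
    pe_df.insert(0, "cow", cows)
    return SyntheticHerd(ped, rec, bv_df, pe_df, cfg)


# ---------------------------------------------------------------------------
# focused single- and two-trait designs for parameter-recovery experiments


def _halfsib_pedigree(n_sires: int, daughters_per_sire: int) -> Pedigree:
    parents: dict[str, tuple[str | None, str | None]] = {}
    for j in range(n_sires):
        parents[f"S_{j}"] = (None, None)
    for j in range(n_sires):
        for i in range(daughters_per_sire):
            parents[f"C_{j}_{i}"] = (f"S_{j}", None)
    return Pedigree.from_parent_map(parents)


def simulate_single_trait(
    n_sires: int,
    daughters_per_sire: int,
    records_per_cow: int,
    sigma2_a: float,
    sigma2_pe: float,
    sigma2_e: float,
    mean: float = 0.0,
    seed: int = 1,
):
    """Paternal half-sib design with a single directly simulated trait.

    Returns ``(pedigree, records)`` where records carry columns ``cow``,
    ``parity`` and ``y``; fixed structure is intercept-only, as used in the
    variance-component recovery experiments.
    """
    rng = np.random.default_rng(seed)
    ped = _halfsib_pedigree(n_sires, daughters_per_sire)
    u = simulate_breeding_values(ped, [[sigma2_a]], rng=rng)[:, 0]
    cows = [a for a in ped.ids if a.startswith("C")]
    rows_idx = np.array([ped.index(c) for c in cows])
    pe = rng.normal(0.0, np.sqrt(sigma2_pe), size=len(cows))
    cow_rep = np.repeat(np.arange(len(cows)), records_per_cow)
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=cow_rep.size)
    y = mean + u[rows_idx][cow_rep] + pe[cow_rep] + e
    rec = pd.DataFrame(
        {
            "cow": np.asarray(cows, dtype=object)[cow_rep],
            "parity": np.tile(np.arange(1, records_per_cow + 1), len(cows)),
            "y": y,
        }
    )
    return ped, rec


def simulate_two_traits(
    n_sires: int,
    daughters_per_sire: int,
    records_per_cow: int,
    G_a,
    G_pe,
    R0,
    seed: int = 1,
):
    """Half-sib design with two jointly simulated traits (2x2 true blocks)."""
    rng = np.random.default_rng(seed)
    ped = _halfsib_pedigree(n_sires, daughters_per_sire)
    u = simulate_breeding_values(ped, G_a, rng=rng)
    cows = [a for a in ped.ids if a.startswith("C")]
    rows_idx = np.array([ped.index(c) for c in cows])
    pe = rng.multivariate_normal(np.zeros(2), np.asarray(G_pe), size=len(cows))
    cow_rep = np.repeat(np.arange(len(cows)), records_per_cow)
    e = rng.multivariate_normal(np.zeros(2), np.asarray(R0), size=cow_rep.size)
    Y = u[rows_idx][cow_rep] + pe[cow_rep] + e
    rec = pd.DataFrame(
        {
            "cow": np.asarray(cows, dtype=object)[cow_rep],
            "parity": np.tile(np.arange(1, records_per_cow + 1), len(cows)),
            "y1": Y[:, 0],
            "y2": Y[:, 1],
        }
    )
    return ped, rec


def small_preset(seed: int = 1, **overrides) -> SimulationConfig:
    """~2,000 cows (200 sires x 10 daughters): the desk-scale test preset."""
    return SimulationConfig(seed=seed, n_sires=200, daughters_per_sire=10, **overrides)


def full_preset(seed: int = 1, **overrides) -> SimulationConfig:
    """~17,468 cows (397 sires x 44 daughters): the study-scale preset."""
    return SimulationConfig(seed=seed, n_sires=397, daughters_per_sire=44, **overrides)
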