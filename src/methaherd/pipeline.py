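"""End-to-end orchestration: data -> methane phenotypes -> REML -> reports.

A pipeline run either simulates a herd or loads pedigree/phenotype CSVs,
appends the derived methane phenotypes, prunes the pedigree to a fixed
number of ancestral generations behind the recorded cows (six by default),
fits a univariate repeatability animal model per requested methane trait,
optionally fits bivariate models for trait pairs, and writes report tables
(summary statistics, variance components with heritability/repeatability
and AIC, genetic/phenotypic correlations) plus a machine-readable run log
with versions, seed and REML iteration traces.
"""

from __future__ import annotations

import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import genparams as gp
from . import methane as mt
from . import reml as rm
from .pedigree import build_nrm_inverse, prune_generations, read_pedigree
from .simulate import SimulationConfig, simulate_pedigree, simulate_records

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("methaherd")

KNOWN_TRAITS = mt.METHANE_TRAITS + mt.MILK_TRAITS + ("ecm",)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    # data source: either a simulation config or paths to CSV inputs
    simulation: SimulationConfig | None = None
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    # analysis plan
    traits: tuple[str, ...] = ("mpe1", "mpe2", "mpe3")
    bivariate_pairs: tuple[tuple[str, str], ...] = ()
    fixed_factors: tuple[str, ...] = ("parity", "herd", "year", "season")
    covariates: tuple[str, ...] = ("lactation_length",)
    prune_to_generations: int = 6
    # REML settings
    method: str = "ai"
    max_iter: int = 500
    rtol: float = 1e-8
    ltol: float = 1e-6
    # bookkeeping
    out_dir: str = "results/pipeline"
    seed: int = 1
    log_level: str = "INFO"

    def validate(self) -> None:
        for t in self.traits:
            if t not in KNOWN_TRAITS:
                raise PipelineError(f"config: unknown trait {t!r} (known: {KNOWN_TRAITS})")
        for pair in self.bivariate_pairs:
            if len(pair) != 2:
                raise PipelineError(f"config: bivariate pair {pair!r} must have 2 traits")
            for t in pair:
                if t not in KNOWN_TRAITS:
                    raise PipelineError(f"config: unknown trait {t!r} in bivariate pair")
        if self.simulation is None and not (self.pedigree_path and self.phenotypes_path):
            raise PipelineError(
                "config: provide either a simulation config or pedigree/phenotype paths"
            )
        if self.simulation is None:
            for p in (self.pedigree_path, self.phenotypes_path):
                if not pathlib.Path(p).exists():
                    raise PipelineError(f"config: input path {p!r} does not exist")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "traits": list(self.traits),
            "bivariate_pairs": [list(p) for p in self.bivariate_pairs],
            "fixed_factors": list(self.fixed_factors),
            "covariates": list(self.covariates),
            "prune_to_generations": self.prune_to_generations,
            "method": self.method,
            "max_iter": self.max_iter,
            "rtol": self.rtol,
            "ltol": self.ltol,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "pedigree_path": self.pedigree_path,
            "phenotypes_path": self.phenotypes_path,
            "simulation": self.simulation.to_dict() if self.simulation else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("traits", "fixed_factors", "covariates"):
            if key in d:
                d[key] = tuple(d[key])
        if "bivariate_pairs" in d:
            d["bivariate_pairs"] = tuple(tuple(p) for p in d["bivariate_pairs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("data")
def _load_data(cfg: PipelineConfig, out: pathlib.Path):
    if cfg.simulation is not None:
        sim_cfg = cfg.simulation
        log.info("simulating herd: %d sires x %d daughters, seed %d",
                 sim_cfg.n_sires, sim_cfg.daughters_per_sire, sim_cfg.seed)
        ped = simulate_pedigree(sim_cfg)
        herd = simulate_records(ped, sim_cfg)
        herd.write(out / "data")
        return herd.pedigree, herd.records
    ped = read_pedigree(cfg.pedigree_path)
    rec = pd.read_csv(cfg.phenotypes_path)
    return ped, rec


@_stage("predict-methane")
def _ensure_methane(records: pd.DataFrame) -> pd.DataFrame:
    if all(c in records.columns for c in mt.METHANE_TRAITS):
        return records
    return mt.add_methane_columns(records)


@_stage("pedigree")
def _prepare_pedigree(ped, records, g):
    focal = set(records["cow"])
    pruned = prune_generations(ped, focal, g=g)
    log.info("pedigree pruned to %d generations: %d -> %d animals", g, len(ped), len(pruned))
    return pruned, build_nrm_inverse(pruned)


@_stage("fit")
def _fit_all(cfg, dm_cache, records, ped, Ainv):
    def design():
        spec = rm.ModelSpec(
            fixed_factors=cfg.fixed_factors, covariates=cfg.covariates
        )
        return rm.build_design(records, ped, spec)

    if "dm" not in dm_cache:
        dm_cache["dm"] = design()
    dm = dm_cache["dm"]
    uni = []
    for t in cfg.traits:
        t0 = time.time()
        vc = rm.reml_univariate(
            dm, Ainv, records[t], trait=t, method=cfg.method,
            max_iter=cfg.max_iter, rtol=cfg.rtol, ltol=cfg.ltol,
        )
        log.info("univariate %s: h2=%.3f r=%.3f logL=%.1f (%d iters, %.1fs)",
                 t, gp.heritability(vc), gp.repeatability(vc), vc.logL,
                 vc.iterations, time.time() - t0)
        uni.append(vc)
    biv = []
    for tx, ty in cfg.bivariate_pairs:
        t0 = time.time()
        fit = rm.reml_bivariate(
            dm, Ainv, records[tx], records[ty], traits=(tx, ty),
            method=cfg.method, max_iter=cfg.max_iter, rtol=cfg.rtol, ltol=cfg.ltol,
        )
        log.info("bivariate %s-%s: rg=%.3f rp=%.3f (%d iters, %.1fs)",
                 tx, ty, fit.rg(), fit.rp(), fit.iterations, time.time() - t0)
        biv.append(fit)
    return uni, biv


@_stage("report")
def _report(cfg, records, uni, biv, out: pathlib.Path):
    tables = gp.report_tables(records, uni, biv, out_dir=out)
    return tables


def run_pipeline(cfg: PipelineConfig):
    """Run the full analysis; returns the dict of report tables.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Re-running with the same config and seed reproduces every output file.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ped, records = _load_data(cfg, out)
    records = _ensure_methane(records)
    pruned, Ainv = _prepare_pedigree(ped, records, cfg.prune_to_generations)
    uni, biv = _fit_all(cfg, {}, records, pruned, Ainv)
    tables = _report(cfg, records, uni, biv, out)

    run_log = {
        "config": cfg.to_dict(),
        "versions": _versions(),
        "n_records": int(len(records)),
        "n_cows": int(records["cow"].nunique()),
        "n_animals_pruned_pedigree": int(len(pruned)),
        "univariate": [
            {
                "trait": vc.trait,
                "converged": bool(vc.converged),
                "iterations": int(vc.iterations),
                "logL_trace": [float(x) for x in vc.logL_history],
            }
            for vc in uni
        ],
        "bivariate": [
            {
                "traits": list(fit.traits),
                "converged": bool(fit.converged),
                "iterations": int(fit.iterations),
                "logL_trace": [float(x) for x in fit.logL_history],
            }
            for fit in biv
        ],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)
    return tables


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "methaherd": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
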