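"""Genetic parameters derived from (co)variance components.

For a repeatability animal model with additive (a), permanent-environment
(pe) and residual (e) variances, the phenotypic variance is
``sP2 = s2a + s2pe + s2e`` and

* heritability        ``h2 = s2a / sP2``
* repeatability       ``r  = (s2a + s2pe) / sP2``  (an upper bound on h2)
* genetic correlation ``rg = covG / sqrt(s2gx * s2gy)``
* phenotypic corr.    ``rp = covP / sqrt(sP2x * sP2y)`` with
  ``covP = covG + covPE + covR``.

Standard errors of the ratios are first-order delta-method approximations
from the sampling covariance of the components (the inverse average-
information matrix reported by the REML fits).  Rounding happens only in
the reporting layer; full precision propagates internally.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "heritability",
    "repeatability",
    "correlation",
    "heritability_se",
    "repeatability_se",
    "correlation_se",
    "summary_table",
    "components_table",
    "correlation_table",
    "report_tables",
]


def _components(vc):
    """Accept a VarianceComponents-like object or a 3-sequence."""
    if hasattr(vc, "sigma2_a"):
        comps = np.array([vc.sigma2_a, vc.sigma2_pe, vc.sigma2_e], dtype=float)
    else:
        comps = np.asarray(vc, dtype=float)
    if comps.shape != (3,):
        raise ValueError("expected three variance components (a, pe, e)")
    if np.any(comps < 0):
        raise ValueError("variance components must be non-negative")
    if comps.sum() <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return comps


def heritability(vc) -> float:
    """h2 = s2a / (s2a + s2pe + s2e)."""
    a, pe, e = _components(vc)
    return a / (a + pe + e)


def repeatability(vc) -> float:
    """r = (s2a + s2pe) / (s2a + s2pe + s2e)."""
    a, pe, e = _components(vc)
    return (a + pe) / (a + pe + e)


def correlation(cov: float, var_x: float, var_y: float) -> float:
    """cov / sqrt(var_x * var_y), clipped to [-1, 1] with a warning."""
    if var_x <= 0 or var_y <= 0:
        raise ValueError("variances must be positive")
    r = cov / np.sqrt(var_x * var_y)
    if abs(r) > 1.0 + 1e-6:
        warnings.warn(
            f"correlation {r:.6f} outside [-1, 1]; clipping", stacklevel=2
        )
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# delta-method standard errors


def _ratio_se(comps, weights_num, cov):
    """SE of (w_num . comps) / (1 . comps) by the delta method."""
    if cov is None:
        return float("nan")
    cov = np.asarray(cov, dtype=float)
    total = comps.sum()
    num = float(weights_num @ comps)
    grad = (weights_num * total - num) / total**2
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def heritability_se(vc, cov=None) -> float:
    """Delta-method SE of h2; ``cov`` defaults to the fit's AI-based matrix."""
    comps = _components(vc)
    cov = cov if cov is not None else getattr(vc, "cov_params", None)
    return _ratio_se(comps, np.array([1.0, 0.0, 0.0]), cov)


def repeatability_se(vc, cov=None) -> float:
    comps = _components(vc)
    cov = cov if cov is not None else getattr(vc, "cov_params", None)
    return _ratio_se(comps, np.array([1.0, 1.0, 0.0]), cov)


def correlation_se(cov_xy, var_x, var_y, cov_params) -> float:
    """Delta-method SE of cov/sqrt(vx*vy).

    ``cov_params`` is the 3x3 sampling covariance of (var_x, cov_xy, var_y).
    """
    if cov_params is None:
        return float("nan")
    r = cov_xy / np.sqrt(var_x * var_y)
    grad = np.array(
        [-0.5 * r / var_x, 1.0 / np.sqrt(var_x * var_y), -0.5 * r / var_y]
    )
    cov_params = np.asarray(cov_params, dtype=float)
    return float(np.sqrt(max(grad @ cov_params @ grad, 0.0)))


# ---------------------------------------------------------------------------
# report tables (summary-statistics, component and correlation analogues)


def summary_table(records: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait mean/SD/min/max plus cow and record counts."""
    if traits is None:
        traits = [
            c
            for c in (
                "milk",
                "fat",
                "protein",
                "lactose",
                "dry_matter",
                "mpe1",
                "mpe2",
                "mpe3",
            )
            if c in records.columns
        ]
    rows = []
    n_cows = records["cow"].nunique() if "cow" in records.columns else len(records)
    for t in traits:
        v = records[t].to_numpy(dtype=float)
        rows.append(
            {
                "trait": t,
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
                "n_cows": n_cows,
                "n_records": len(v),
            }
        )
    return pd.DataFrame(rows)


def components_table(fits) -> pd.DataFrame:
    """Variance components, h2 (SE), r (SE) and AIC per univariate fit.

    Ratios are rounded to 2 decimals in dedicated display columns; raw
    values are kept alongside.  The AIC column ranks models: smallest is
    preferred.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to report")
    rows = []
    for vc in fits:
        h2 = heritability(vc)
        r = repeatability(vc)
        rows.append(
            {
                "trait": vc.trait,
                "sigma2_a": vc.sigma2_a,
                "sigma2_pe": vc.sigma2_pe,
                "sigma2_e": vc.sigma2_e,
                "h2": h2,
                "h2_se": heritability_se(vc),
                "repeatability": r,
                "repeatability_se": repeatability_se(vc),
                "h2_2dp": round(h2, 2),
                "repeatability_2dp": round(r, 2),
                "logL": vc.logL,
                "aic": vc.aic,
                "converged": vc.converged,
                "iterations": vc.iterations,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(bivariate_fits) -> pd.DataFrame:
    """Genetic and phenotypic correlations per trait pair (2 dp display)."""
    fits = list(bivariate_fits)
    if not fits:
        raise ValueError("no fits to report")
    rows = []
    for fit in fits:
        Ga, Gpe, R = fit.G_a, fit.G_pe, fit.R
        P = Ga + Gpe + R
        rg = correlation(Ga[0, 1], Ga[0, 0], Ga[1, 1])
        rp = correlation(P[0, 1], P[0, 0], P[1, 1])
        rows.append(
            {
                "trait_x": fit.traits[0],
                "trait_y": fit.traits[1],
                "rg": rg,
                "rg_se": fit.rg_se(),
                "rp": rp,
                "rg_2dp": round(rg, 2),
                "rp_2dp": round(rp, 2),
                "logL": fit.logL,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def report_tables(
    records: pd.DataFrame | None,
    univariate_fits,
    bivariate_fits=(),
    out_dir=None,
):
    """Render the report bundle; optionally write CSVs under ``out_dir``.

    Returns a dict of DataFrames keyed ``summary``, ``components``,
    ``correlations`` (the last only when bivariate fits are supplied).
    """
    tables: dict[str, pd.DataFrame] = {}
    if records is not None:
        tables["summary"] = summary_table(records)
    tables["components"] = components_table(univariate_fits)
    bivariate_fits = list(bivariate_fits)
    if bivariate_fits:
        tables["correlations"] = correlation_table(bivariate_fits)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
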