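"""Indirect methane phenotypes from lactation milk records.

Enteric methane is rarely measured directly at population scale; instead it
is predicted from routinely recorded milk traits.  Three published linear
prediction equations are implemented, all returning grams of methane per
lactation:

* MPE1: from milk yield alone, ``299 + 2.73 * MY``
* MPE2: from energy-corrected milk, ``259 + 3.86 * ECM``
* MPE3: from ECM and milk protein concentration,
  ``150 + 4.31 * ECM + 28.3 * CPC``

with ECM (kg/lactation) = ``0.327*milk + 12.95*fat + 7.2*protein`` and CPC
(%) = ``100 * protein / milk``.  The equations are applied to per-lactation
totals.  Dividing a per-lactation total by the lactation length in days
(310 on average in the target population) gives g/day.

All functions accept scalars or numpy arrays.  The published standard
errors of the equation coefficients are kept as metadata only
(:data:`EQUATION_COEFFICIENTS`); they are not propagated into phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ecm",
    "cpc",
    "mpe1",
    "mpe2",
    "mpe3",
    "predict_methane",
    "add_methane_columns",
    "per_day",
    "MethanePhenotypes",
    "EQUATION_COEFFICIENTS",
    "METHANE_TRAITS",
    "MILK_TRAITS",
    "MEAN_LACTATION_DAYS",
]

#: intercept/slope (value, standard error) for each prediction equation
EQUATION_COEFFICIENTS = {
    "mpe1": {"intercept": (299.0, 12.1), "milk": (2.73, 0.171)},
    "mpe2": {"intercept": (259.0, 11.1), "ecm": (3.86, 0.167)},
    "mpe3": {"intercept": (150.0, 16.1), "ecm": (4.31, 0.172), "cpc": (28.3, 3.20)},
}

METHANE_TRAITS = ("mpe1", "mpe2", "mpe3")
MILK_TRAITS = ("milk", "fat", "protein", "lactose", "dry_matter")

#: mean lactation length (days) used for per-day summaries
MEAN_LACTATION_DAYS = 310


@dataclass(frozen=True)
class MethanePhenotypes:
    """Derived phenotypes for one lactation (all methane in g/lactation)."""

    ecm: float
    cpc: float
    mpe1: float
    mpe2: float
    mpe3: float


def _nonneg(name, value):
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError(f"{name} must be non-negative")
    return value


def ecm(milk, fat, protein):
    """Energy-corrected milk, kg/lactation."""
    milk = _nonneg("milk", milk)
    fat = _nonneg("fat", fat)
    protein = _nonneg("protein", protein)
    return 0.327 * milk + 12.95 * fat + 7.2 * protein


def cpc(milk, protein):
    """Milk protein concentration, percent of milk yield."""
    milk = np.asarray(milk, dtype=float)
    protein = _nonneg("protein", protein)
    if np.any(milk <= 0):
        raise ValueError("milk must be positive to compute a concentration")
    return 100.0 * protein / milk


def mpe1(milk):
    """Methane (g/lactation) predicted from milk yield."""
    return 299.0 + 2.73 * _nonneg("milk", milk)


def mpe2(energy_corrected_milk):
    """Methane (g/lactation) predicted from energy-corrected milk."""
    return 259.0 + 3.86 * _nonneg("ecm", energy_corrected_milk)


def mpe3(energy_corrected_milk, protein_concentration):
    """Methane (g/lactation) predicted from ECM and protein concentration."""
    return (
        150.0
        + 4.31 * _nonneg("ecm", energy_corrected_milk)
        + 28.3 * _nonneg("cpc", protein_concentration)
    )


def predict_methane(milk, fat, protein):
    """All derived phenotypes for one lactation (scalars) -> MethanePhenotypes."""
    e = float(ecm(milk, fat, protein))
    c = float(cpc(milk, protein))
    return MethanePhenotypes(
        ecm=e, cpc=c, mpe1=float(mpe1(milk)), mpe2=float(mpe2(e)), mpe3=float(mpe3(e, c))
    )


def add_methane_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Append ``ecm, cpc, mpe1, mpe2, mpe3`` columns to a phenotype table.

    ``records`` must carry ``milk``, ``fat`` and ``protein`` columns
    (kg/lactation).  Returns a copy; the input is not modified.
    """
    for col in ("milk", "fat", "protein"):
        if col not in records.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    out = records.copy()
    e = ecm(out["milk"].to_numpy(), out["fat"].to_numpy(), out["protein"].to_numpy())
    c = cpc(out["milk"].to_numpy(), out["protein"].to_numpy())
    out["ecm"] = e
    out["cpc"] = c
    out["mpe1"] = mpe1(out["milk"].to_numpy())
    out["mpe2"] = mpe2(e)
    out["mpe3"] = mpe3(e, c)
    return out


def per_day(total, days=MEAN_LACTATION_DAYS):
    """Convert a per-lactation total (g) to g/day."""
    total = np.asarray(total, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("days must be positive")
    return total / days
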