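"""Exchange-rate quantification and growth estimation.

Medium metabolites are absolutely quantified against five-point standard
calibration curves (0.25x, 0.5x, 1x, 2x, 4x of the nominal medium
concentration); the spent-medium / cell-free difference, normalized to the
mean of day-0 and day-2 protein and to the incubation time, gives the
exchange rate in nmol · (μg protein)⁻¹ · day⁻¹ — positive for secretion,
negative for consumption.  Doubling times come from a log-linear fit of
growth measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "ExchangeRateRecord",
    "fit_calibration",
    "quantify_medium",
    "exchange_rate",
    "percent_glucose_to_lactate",
    "doubling_time",
    "exchange_rate_table",
]

#: the five dilution factors of the standard calibration design
STANDARD_LEVELS = (0.25, 0.5, 1.0, 2.0, 4.0)


class CalibrationError(ValueError):
    """The standards are uninformative (degenerate design or flat response)."""


@dataclass
class CalibrationCurve:
    """OLS line area = slope · concentration + intercept, with inverse
    prediction for absolute quantification."""

    metabolite: str
    slope: float
    intercept: float
    r_squared: float
    concentrations: np.ndarray
    areas: np.ndarray

    @property
    def usable(self) -> bool:
        return self.slope > 0

    def inverse(self, area: float) -> float:
        """Predicted concentration (μM) for a measured area."""
        if not self.usable:
            raise CalibrationError(f"{self.metabolite}: non-positive slope")
        return (area - self.intercept) / self.slope


def fit_calibration(
    concentrations: Sequence[float],
    areas: Sequence[float],
    metabolite: str = "",
) -> CalibrationCurve:
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if len(conc) < 2 or len(conc) != len(area):
        raise CalibrationError(f"{metabolite}: need >= 2 matched standard levels")
    if np.ptp(conc) == 0:
        raise CalibrationError(f"{metabolite}: zero variance in standard concentrations")
    if np.ptp(area) == 0:
        raise CalibrationError(f"{metabolite}: flat response, uninformative curve")
    fit = sps.linregress(conc, area)
    curve = CalibrationCurve(
        metabolite=metabolite,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        concentrations=conc,
        areas=area,
    )
    if not curve.usable:
        raise CalibrationError(f"{metabolite}: fitted slope {curve.slope:.3g} <= 0")
    return curve


def quantify_medium(
    area: float, curve: CalibrationCurve, well_volume_ml: float
) -> float:
    """Amount in the well: inverse-predicted μM × ml = nmol.

    Negative inverse predictions (noise below the blank) are clipped to
    zero with a warning — concentrations are physical quantities.
    """
    if well_volume_ml <= 0:
        raise ValueError("well volume must be positive")
    conc = curve.inverse(area)
    if conc < 0:
        warnings.warn(
            f"{curve.metabolite}: negative predicted concentration "
            f"{conc:.3g} μM clipped to 0",
            stacklevel=2,
        )
        conc = 0.0
    return conc * well_volume_ml


def exchange_rate(
    nmol_spent: float,
    nmol_cellfree: float,
    prot_day0_ug: float,
    prot_day2_ug: float,
    duration_days: float = 2.0,
) -> float:
    """(spent − cell-free) / mean protein / time, nmol·μg⁻¹·day⁻¹.

    Positive values are secretion, negative consumption.  ``duration_days``
    defaults to the 48 h incubation; pass 1.0 to report per-incubation
    amounts instead of daily rates.
    """
    if prot_day0_ug <= 0 or prot_day2_ug <= 0:
        raise ValueError("protein measurements must be positive")
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    mean_prot = (prot_day0_ug + prot_day2_ug) / 2.0
    return (nmol_spent - nmol_cellfree) / mean_prot / duration_days


@dataclass
class ExchangeRateRecord:
    metabolite: str
    nmol_spent: float
    nmol_cellfree: float
    prot_day0_ug: float
    prot_day2_ug: float
    duration_days: float
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.rate = exchange_rate(
            self.nmol_spent,
            self.nmol_cellfree,
            self.prot_day0_ug,
            self.prot_day2_ug,
            self.duration_days,
        )


def percent_glucose_to_lactate(glucose_rate: float, lactate_rate: float) -> float:
    """Share of consumed glucose leaving as lactate, in percent.

    Lactate is multiplied by 0.5 for the 1 glucose : 2 lactate glycolytic
    stoichiometry.  Requires net glucose consumption (negative rate).
    """
    if glucose_rate >= 0:
        raise ValueError("glucose rate must be negative (net consumption)")
    if lactate_rate < 0:
        raise ValueError("lactate rate must be non-negative (net secretion)")
    return 100.0 * (0.5 * lactate_rate) / abs(glucose_rate)


def doubling_time(counts: Sequence[float], times_h: Sequence[float]) -> float:
    """Doubling time (h) from a least-squares fit of log2(count) vs time.

    Returns ``math.inf`` when the fitted slope is non-positive (no growth).
    """
    c = np.asarray(counts, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if len(c) < 2 or len(c) != len(t):
        raise ValueError("need >= 2 matched (count, time) points")
    if np.any(c <= 0):
        raise ValueError("counts must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    slope = np.polyfit(t, np.log2(c), 1)[0]
    if slope <= 1e-12:  # flat or shrinking: no doubling
        return math.inf
    return 1.0 / slope


def exchange_rate_table(
    spent: pd.DataFrame,
    cellfree_nmol: dict[str, float],
    protein: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    well_volume_ml: float = 0.8,
    duration_days: float = 2.0,
) -> pd.DataFrame:
    """Per-donor exchange rates from measured tables.

    ``spent``: columns donor, oxygen, metabolite, area.  ``protein``:
    columns donor, oxygen, day (0 or 2), ug.  ``cellfree_nmol``: per-
    metabolite reference amounts already quantified.  Returns one row per
    donor × oxygen × metabolite with the rate and its inputs.
    """
    prot = protein.pivot_table(index=["donor", "oxygen"], columns="day", values="ug")
    rows = []
    for (donor, oxygen, met), grp in spent.groupby(["donor", "oxygen", "metabolite"]):
        if met not in curves:
            continue
        area = float(grp["area"].mean())
        nmol = quantify_medium(area, curves[met], well_volume_ml)
        p0 = float(prot.loc[(donor, oxygen), 0])
        p2 = float(prot.loc[(donor, oxygen), 2])
        rec = ExchangeRateRecord(
            metabolite=met,
            nmol_spent=nmol,
            nmol_cellfree=cellfree_nmol[met],
            prot_day0_ug=p0,
            prot_day2_ug=p2,
            duration_days=duration_days,
        )
        rows.append(
            {
                "donor": donor,
                "oxygen": oxygen,
                "metabolite": met,
                "nmol_spent": rec.nmol_spent,
                "nmol_cellfree": rec.nmol_cellfree,
                "prot_day0_ug": p0,
                "prot_day2_ug": p2,
                "duration_days": duration_days,
                "rate_nmol_per_ug_per_day": rec.rate,
            }
        )
    return pd.DataFrame(rows)
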