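"""IC50 machinery: densitometric calibration and dose-response fitting.

Two assay read-outs are covered:

* TLC-bioautography: enzyme-inhibition zones on a TLC plate are quantified
  densitometrically; a linear calibration (peak area vs applied amount)
  is inverted at half of a maximal-inhibition reference response and the
  solved amount converted to a molar concentration through an explicit
  unit-conversion record.
* MTT viability: blank-corrected optical densities give viability
  percentages; the IC50 is the concentration at 50% response, obtained
  from a four-parameter logistic (4PL) fit with a linear-interpolation
  fallback between the bracketing doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


# ---------------------------------------------------------------------------
# Linear densitometry calibration

@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line response = slope * amount + intercept."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...] = ()


def fit_linear_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Least-squares line through (amount, response) points.

    Requires >= 2 points with at least two distinct amounts; with exactly
    two points R^2 = 1 by construction.
    """
    pts = [(float(a), float(r)) for a, r in points]
    if len(pts) < 2:
        raise ValueError("need >= 2 calibration points")
    x = np.array([a for a, _ in pts])
    y = np.array([r for _, r in pts])
    if np.ptp(x) == 0:
        raise ValueError("all calibration amounts identical")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            r_squared=r2, points=tuple(pts))


# ---------------------------------------------------------------------------
# Viability

def viability_percent(od_treated: float, od_control: float,
                      od_blank: float = 0.0) -> float:
    """Blank-corrected viability: 100 * (ODt - ODb) / (ODc - ODb)."""
    if od_control <= od_blank:
        raise ValueError(
            f"od_control ({od_control}) must exceed od_blank ({od_blank})")
    return 100.0 * (od_treated - od_blank) / (od_control - od_blank)


def inhibition_percent(od_treated: float, od_control: float,
                       od_blank: float = 0.0) -> float:
    """Complement of viability: inhibition% + viability% = 100."""
    return 100.0 - viability_percent(od_treated, od_control, od_blank)


# ---------------------------------------------------------------------------
# Dose-response and IC50

def four_pl(x, bottom, top, ic50, hill):
    """Four-parameter logistic, decreasing for hill > 0."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(x, dtype=float) / ic50) ** hill)


@dataclass
class DoseResponseCurve:
    """Sorted positive doses with finite responses (viability %, typically)."""

    doses: np.ndarray
    responses: np.ndarray

    def __init__(self, doses, responses):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape or doses.ndim != 1:
            raise ValueError("doses and responses must be 1-D and equal length")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if not np.all(np.isfinite(responses)):
            raise ValueError("responses must be finite")
        order = np.argsort(doses)
        self.doses = doses[order]
        self.responses = responses[order]


@dataclass(frozen=True)
class IC50Result:
    ic50: float
    method: str                      # "4pl" | "interpolation"
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    midpoint: float
    hill: float
    rss: float

    def solve_response(self, level: float) -> float:
        """Concentration at which the fitted curve crosses ``level``."""
        if not min(self.bottom, self.top) < level < max(self.bottom, self.top):
            raise ValueError(f"level {level} outside fitted asymptotes "
                             f"[{self.bottom}, {self.top}]")
        ratio = (self.top - level) / (level - self.bottom)
        return self.midpoint * ratio ** (1.0 / self.hill)


def fit_four_pl(doses, responses, seed: int = 0,
                bottom_bounds=(0.0, 50.0), top_bounds=(50.0, 120.0)) -> FourPLFit:
    """Seeded multi-start bounded least-squares 4PL fit.

    Starts are laid over a grid of plausible midpoints (spanning the dose
    range on a log scale) and Hill slopes, with seeded jitter; the best
    residual sum of squares wins.  Bounds keep the asymptotes on the
    viability scale (bottom in [0, 50], top in [50, 120]).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    rng = np.random.default_rng(seed)
    lo = np.array([bottom_bounds[0], top_bounds[0], doses.min() / 100.0, 0.05])
    hi = np.array([bottom_bounds[1], top_bounds[1], doses.max() * 100.0, 10.0])

    def residuals(theta):
        return four_pl(doses, *theta) - responses

    best = None
    mid_grid = np.geomspace(doses.min(), doses.max(), 4)
    for mid in mid_grid:
        for hill in (0.5, 1.0, 2.0):
            x0 = np.array([
                float(np.clip(responses.min(), *bottom_bounds)),
                float(np.clip(responses.max(), *top_bounds)),
                mid * math.exp(rng.normal(scale=0.05)),
                hill,
            ])
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(residuals, x0, bounds=(lo, hi))
            rss = float(2 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    assert best is not None
    rss, (bottom, top, midpoint, hill) = best
    return FourPLFit(bottom=float(bottom), top=float(top),
                     midpoint=float(midpoint), hill=float(hill), rss=rss)


def _interpolate_ic50(curve: DoseResponseCurve, level: float) -> float:
    # linear in concentration between the bracketing doses
    d, r = curve.doses, curve.responses
    for i in range(len(d) - 1):
        r0, r1 = r[i], r[i + 1]
        if (r0 - level) * (r1 - level) <= 0 and r0 != r1:
            return float(d[i] + (r0 - level) / (r0 - r1) * (d[i + 1] - d[i]))
    raise ValueError("IC50 not identifiable in tested range")


def ic50_dose_response(curve: DoseResponseCurve, level: float = 50.0,
                       method: str = "auto", seed: int = 0) -> IC50Result:
    """Concentration at the 50% response level of a dose-response curve.

    The primary path fits a 4PL by least squares and solves it at ``level``;
    if the fit cannot cross the level (asymptotes on one side) or ``method``
    is ``"interpolation"``, the bracketing doses are interpolated linearly
    in concentration.  Requires responses on both sides of the level.

    Raises
    ------
    ValueError
        If no pair of doses brackets the requested level.
    """
    r = curve.responses
    if not (r.min() < level < r.max()):
        raise ValueError("IC50 not identifiable in tested range: responses "
                         f"do not bracket {level}%")
    if method not in ("auto", "4pl", "interpolation"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "4pl"):
        fit = fit_four_pl(curve.doses, curve.responses, seed=seed)
        try:
            ic50 = fit.solve_response(level)
            return IC50Result(ic50=ic50, method="4pl", params={
                "bottom": fit.bottom, "top": fit.top,
                "midpoint": fit.midpoint, "hill": fit.hill, "rss": fit.rss})
        except ValueError:
            if method == "4pl":
                raise
    return IC50Result(ic50=_interpolate_ic50(curve, level),
                      method="interpolation")


# ---------------------------------------------------------------------------
# TLC-bioautography IC50

@dataclass(frozen=True)
class TLCConversion:
    """Explicit unit path from a calibration amount to a molar concentration.

    The calibration x-axis is an applied volume in µL of a stock solution;
    the solved volume is converted to mass via ``stock_conc_mg_per_ml``,
    to moles via ``molar_mass_g_per_mol``, and to molarity over
    ``zone_volume_ul`` (the effective volume defining the local
    concentration on the plate).  Every constant is explicit so that any
    laboratory convention can be reproduced.
    """

    molar_mass_g_per_mol: float
    stock_conc_mg_per_ml: float
    zone_volume_ul: float

    def amount_ul_to_micromolar(self, volume_ul: float) -> float:
        for name in ("molar_mass_g_per_mol", "stock_conc_mg_per_ml",
                     "zone_volume_ul"):
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ValueError(f"conversion constant {name} must be positive")
        mass_mg = volume_ul * self.stock_conc_mg_per_ml / 1000.0
        moles = mass_mg / 1000.0 / self.molar_mass_g_per_mol
        litres = self.zone_volume_ul * 1e-6
        return moles / litres * 1e6


def ic50_tlc(calibration: CalibrationCurve, reference_response: float,
             conversion: TLCConversion) -> float:
    """TLC-bioautography IC50 in µM.

    Solves the calibration line for the amount giving half of the supplied
    maximal-inhibition reference response, then converts that amount to a
    molar concentration through the explicit ``conversion`` record.
    """
    if calibration.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    half = 0.5 * reference_response
    amount = (half - calibration.intercept) / calibration.slope
    if amount <= 0:
        raise ValueError(
            f"solved amount {amount:.4g} <= 0: half-reference response below "
            "the calibration intercept")
    return conversion.amount_ul_to_micromolar(amount)


def solve_calibration_amount(calibration: CalibrationCurve,
                             response: float) -> float:
    """Amount at which the calibration line reaches ``response``."""
    if calibration.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    return (response - calibration.intercept) / calibration.slope


# ---------------------------------------------------------------------------
# Plate/densitometry table IO

def read_plate_csv(path) -> pd.DataFrame:
    """Microplate table with columns well, dose, od (control/blank rows have
    dose 0 and well labels 'control'/'blank')."""
    df = pd.read_csv(path)
    missing = sorted({"well", "dose", "od"} - set(df.columns))
    if missing:
        raise ValueError(f"plate CSV missing columns: {missing}")
    return df


def plate_to_dose_response(plate: pd.DataFrame) -> DoseResponseCurve:
    """Average OD per dose, blank-correct against the plate's control and
    blank wells, and return the viability dose-response curve."""
    blanks = plate[plate["well"].str.startswith("blank")]
    controls = plate[plate["well"].str.startswith("control")]
    if blanks.empty or controls.empty:
        raise ValueError("plate must contain 'blank' and 'control' wells")
    od_blank = float(blanks["od"].mean())
    od_control = float(controls["od"].mean())
    treated = plate[~plate["well"].str.startswith(("blank", "control"))]
    grouped = treated.groupby("dose")["od"].mean()
    doses = grouped.index.to_numpy(dtype=float)
    viability = np.array([
        viability_percent(od, od_control, od_blank) for od in grouped.to_numpy()])
    return DoseResponseCurve(doses, viability)


def read_densitometry_csv(path) -> list[tuple[float, float]]:
    """Densitometry table with columns lane, amount, peak_area; replicate
    lanes at one amount are averaged."""
    df = pd.read_csv(path)
    missing = sorted({"amount", "peak_area"} - set(df.columns))
    if missing:
        raise ValueError(f"densitometry CSV missing columns: {missing}")
    grouped = df.groupby("amount")["peak_area"].mean()
    return [(float(a), float(r)) for a, r in grouped.items()]
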