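"""Chromatographic lipophilicity via the Soczewinski-Wachtmeister relation.

Retention of a solute on a membrane-like HPLC stationary phase (IAM, CHOL,
ISRP) falls linearly with the volume fraction phi of the organic modifier:

    log k = log kw - s * phi

The intercept log kw (log10 retention factor extrapolated to pure water) is
the chromatographic lipophilicity descriptor; the slope magnitude s is
characteristic of the solute/system pair.  This module converts raw
retention times into retention factors, aggregates replicates, and fits the
linear relation by ordinary least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetentionMeasurement:
    """One injection: organic-modifier fraction and retention/dead times (min)."""

    phi: float
    t_retention: float
    t_dead: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.phi < 1:
            raise ValueError(f"phi must satisfy 0 <= phi < 1, got {self.phi}")
        if self.t_dead <= 0:
            raise ValueError(f"t_dead must be positive, got {self.t_dead}")
        if self.t_retention < self.t_dead:
            raise ValueError(
                f"t_retention ({self.t_retention}) < t_dead ({self.t_dead}): "
                "analyte not retained")


def retention_factor(t_retention: float, t_dead: float) -> float:
    """Dimensionless retention factor k = (tR - t0) / t0."""
    if t_dead <= 0:
        raise ValueError(f"t_dead must be positive, got {t_dead}")
    if t_retention < t_dead:
        raise ValueError(
            f"t_retention ({t_retention}) < t_dead ({t_dead}): analyte elutes "
            "before the dead-time marker")
    return (t_retention - t_dead) / t_dead


def log_retention_factor(t_retention: float, t_dead: float) -> float:
    """log10 k; raises for k = 0 (retention time equal to dead time)."""
    k = retention_factor(t_retention, t_dead)
    if k == 0:
        raise ValueError("k = 0 (t_retention == t_dead): log k undefined")
    return math.log10(k)


def _normalize_phi(phi: float) -> float:
    # accept percent notation (75 -> 0.75) from CSV inputs
    if phi >= 1.0:
        logger.info("phi value %s >= 1 interpreted as percent -> %s", phi, phi / 100.0)
        return phi / 100.0
    return phi


@dataclass
class RetentionSeries:
    """Replicate-averaged (phi, log k) observations for one compound/system."""

    system_name: str
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = sorted(self.points)
        phis = [p for p, _ in self.points]
        if len(set(phis)) != len(phis):
            raise ValueError("phi values must be distinct after aggregation")

    @classmethod
    def from_measurements(cls, system_name: str,
                          measurements: Iterable[RetentionMeasurement],
                          ) -> "RetentionSeries":
        """Average replicate retention times per phi, then take log k.

        Times are averaged before the k/log k transform (mean of times, not
        mean of log k), matching how replicate injections are reduced on the
        instrument side.
        """
        by_phi: dict[float, list[RetentionMeasurement]] = {}
        for m in measurements:
            by_phi.setdefault(m.phi, []).append(m)
        if not by_phi:
            raise ValueError("no measurements supplied")
        points = []
        for phi, group in by_phi.items():
            t_r = float(np.mean([m.t_retention for m in group]))
            t_0 = float(np.mean([m.t_dead for m in group]))
            points.append((phi, log_retention_factor(t_r, t_0)))
        return cls(system_name=system_name, points=points)

    @property
    def phi(self) -> np.ndarray:
        return np.array([p for p, _ in self.points])

    @property
    def logk(self) -> np.ndarray:
        return np.array([lk for _, lk in self.points])


@dataclass(frozen=True)
class SWFit:
    """Fitted Soczewinski-Wachtmeister line for one system.

    ``s`` is stored as the positive slope magnitude of the (normally)
    decreasing retention line.  ``retention_decreases`` is False when the
    fitted raw slope is non-negative, which violates reversed-phase
    retention theory; the fit is then flagged rather than rejected.
    """

    system_name: str
    logkw: float
    s: float
    r_squared: float
    residual_se: float
    n_points: int
    retention_decreases: bool = True


def fit_soczewinski_wachtmeister(series: RetentionSeries) -> SWFit:
    """OLS fit of log k on phi; intercept is log kw, slope magnitude is s.

    Requires >= 2 distinct phi values.  With exactly two points the line is
    exact (R^2 = 1, residual SE = 0).
    """
    phi, logk = series.phi, series.logk
    n = len(phi)
    if n < 2:
        raise ValueError("need >= 2 distinct phi values to fit")
    slope, intercept = np.polyfit(phi, logk, 1)
    fitted = intercept + slope * phi
    ss_res = float(np.sum((logk - fitted) ** 2))
    ss_tot = float(np.sum((logk - logk.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # guard tiny negative round-off at exactness
    r2 = min(max(r2, 0.0), 1.0)
    residual_se = 0.0 if n <= 2 else math.sqrt(ss_res / (n - 2))
    decreases = slope < 0
    if not decreases:
        logger.warning(
            "system %s: retention does not decrease with phi (slope %.4g); "
            "retention theory violated", series.system_name, slope)
    return SWFit(system_name=series.system_name,
                 logkw=float(intercept),
                 s=float(abs(slope)),
                 r_squared=float(r2),
                 residual_se=float(residual_se),
                 n_points=n,
                 retention_decreases=decreases)


# ---------------------------------------------------------------------------
# CSV interfaces

RETENTION_COLUMNS = ["system", "phi", "t_retention", "t_dead", "replicate"]


def read_retention_csv(path) -> dict[str, RetentionSeries]:
    """Read a retention table (columns system, phi, t_retention, t_dead,
    replicate) and return replicate-averaged series per system.

    phi may be given as a fraction (0.75) or percent (75); percents are
    normalized with a log message.
    """
    df = pd.read_csv(path)
    missing = [c for c in RETENTION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"retention CSV missing columns: {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    series = {}
    for system, group in df.groupby("system"):
        measurements = [
            RetentionMeasurement(phi=_normalize_phi(float(r.phi)),
                                 t_retention=float(r.t_retention),
                                 t_dead=float(r.t_dead),
                                 replicate_id=int(r.replicate))
            for r in group.itertuples()
        ]
        series[str(system)] = RetentionSeries.from_measurements(str(system), measurements)
    return series


def swfit_table(fits: Sequence[SWFit]) -> pd.DataFrame:
    """Tabulate fits with columns system, logkw, s, r_squared (report layout)."""
    return pd.DataFrame(
        [{"system": f.system_name, "logkw": f.logkw, "s": f.s,
          "r_squared": f.r_squared, "residual_se": f.residual_se,
          "n_points": f.n_points} for f in fits])


def write_swfit_csv(fits: Sequence[SWFit], path) -> None:
    swfit_table(fits).to_csv(path, index=False)
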