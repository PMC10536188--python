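"""Blood-brain distribution (logBB) QSAR modelling.

The central model is a three-descriptor multiple linear regression

    logBB = b0 + b1 * dlogP + b2 * logkw + b3 * E

where logkw is the chromatographic lipophilicity descriptor from a
membrane-like system, E is the Abraham excess molar refraction, and dlogP
(the hydrogen-binding potential) is the difference between the
cyclohexane/water partition coefficient logPcw and logkw.  The published
coefficient set (-0.114, -0.098, +0.278, +0.218), trained on 40 compounds
with residual scale S = 0.436, ships as the built-in model ``EQ2``.

Alongside prediction, the module provides the full model-(re)building
machinery: MLR with backward elimination of variables, leave-ten-out
cross-validation (PRESS, RMSECV, R2CV), and a leverage-based applicability
domain.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Default descriptor order of the built-in model.
DEFAULT_DESCRIPTORS = ("delta_logp", "logkw", "E")


def delta_logp(logkw: float, logpcw: float) -> float:
    """Hydrogen-binding potential: logPcw - logkw.

    The larger the gap between the membrane-like lipophilicity (logkw) and
    the purely nonpolar cyclohexane/water partitioning (logPcw), the greater
    the solute's hydrogen-bonding capacity.
    """
    if not (math.isfinite(logkw) and math.isfinite(logpcw)):
        raise ValueError("logkw and logPcw must be finite")
    return logpcw - logkw


@dataclass(frozen=True)
class CompoundDescriptors:
    """Descriptor record for one compound in one membrane-like system.

    ``delta_logp`` is always derived from (logkw, logPcw); it is exposed as
    a property and cannot be set independently.
    """

    logkw: float
    logPcw: float
    E: float
    system: str | None = None

    @property
    def delta_logp(self) -> float:
        return delta_logp(self.logkw, self.logPcw)

    def as_dict(self) -> dict[str, float]:
        return {"delta_logp": self.delta_logp, "logkw": self.logkw, "E": self.E}


@dataclass
class QSARModel:
    """Linear logBB model: coefficients plus validation state.

    ``training_design`` (descriptor matrix of the training set, without the
    intercept column, columns in ``descriptor_names`` order) enables
    leverage-based applicability-domain checks; it is absent for the
    built-in literature model whose training set is not reproduced.
    """

    intercept: float
    coefficients: dict[str, float]
    n_train: int | None = None
    r2: float | None = None
    rmse: float | None = None
    s: float | None = None
    r2_cv: float | None = None
    rmsecv: float | None = None
    press: float | None = None
    r2_pred: float | None = None
    training_design: np.ndarray | None = field(default=None, repr=False)

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    @property
    def ad_leverage_threshold(self) -> float | None:
        """Warning leverage h* = 3 (p + 1) / n."""
        if self.n_train is None:
            return None
        p = len(self.coefficients)
        return 3.0 * (p + 1) / self.n_train

    def _vector(self, d) -> np.ndarray:
        record = d.as_dict() if isinstance(d, CompoundDescriptors) else dict(d)
        missing = [k for k in self.descriptor_names if k not in record]
        if missing:
            raise ValueError(f"missing descriptors: {missing}")
        return np.array([record[k] for k in self.descriptor_names], dtype=float)

    def predict(self, d) -> float:
        x = self._vector(d)
        coef = np.array([self.coefficients[k] for k in self.descriptor_names])
        return float(self.intercept + x @ coef)

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "n_train": self.n_train, "r2": self.r2, "rmse": self.rmse,
            "s": self.s, "r2_cv": self.r2_cv, "rmsecv": self.rmsecv,
            "press": self.press, "r2_pred": self.r2_pred,
            "training_design": (None if self.training_design is None
                                else self.training_design.tolist()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "QSARModel":
        with open(path) as fh:
            payload = json.load(fh)
        design = payload.pop("training_design", None)
        return cls(training_design=None if design is None else np.asarray(design),
                   **payload)


#: Built-in published logBB model (40-compound training set; descriptor
#: order dlogP, logkw, E).  Validation statistics as published; the
#: training design itself is not reproduced, so no applicability domain.
EQ2 = QSARModel(
    intercept=-0.114,
    coefficients={"delta_logp": -0.098, "logkw": 0.278, "E": 0.218},
    n_train=40,
    r2_cv=0.7825,
    r2_pred=0.7402,
    s=0.436,
)


def predict_logbb(model: QSARModel, d) -> float:
    """Predicted logBB for a descriptor record (exactly linear in d)."""
    return model.predict(d)


# ---------------------------------------------------------------------------
# Model building

def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] <= arr.shape[1] + 1:
        raise ValueError(
            f"need n > p + 1 observations, got n={arr.shape[0]}, p={arr.shape[1]}")
    for col in X.columns:
        if np.ptp(np.asarray(X[col], dtype=float)) == 0:
            raise ValueError(f"descriptor {col!r} is constant")
    design = np.column_stack([np.ones(arr.shape[0]), arr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient descriptor matrix")


def fit_mlr_backward(X: pd.DataFrame, y, alpha_remove: float = 0.05) -> QSARModel:
    """MLR with backward elimination of variables.

    Starting from all candidate descriptors, the least significant one
    (largest partial-t p-value above ``alpha_remove``) is removed, one per
    iteration, until every retained descriptor satisfies p <= alpha_remove.
    If every descriptor is eliminated an intercept-only model is returned
    with a warning.

    Returns a :class:`QSARModel` carrying R^2, RMSE (sqrt(SSR/n)), residual
    standard error S (sqrt(SSR/(n - p - 1))) and the retained training
    design for applicability-domain checks.
    """
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    _check_design(X)
    retained = list(X.columns)
    while retained:
        design = sm.add_constant(X[retained].to_numpy(dtype=float))
        fit = sm.OLS(y, design).fit()
        pvalues = fit.pvalues[1:]  # skip intercept
        worst = int(np.argmax(pvalues))
        if pvalues[worst] <= alpha_remove:
            break
        logger.info("backward elimination: dropping %r (p=%.3g)",
                    retained[worst], pvalues[worst])
        retained.pop(worst)
    n = len(y)
    if not retained:
        warnings.warn("all descriptors eliminated; returning intercept-only model")
        resid = y - y.mean()
        ssr = float(resid @ resid)
        return QSARModel(intercept=float(y.mean()), coefficients={}, n_train=n,
                         r2=0.0, rmse=math.sqrt(ssr / n),
                         s=math.sqrt(ssr / (n - 1)))
    design = sm.add_constant(X[retained].to_numpy(dtype=float))
    fit = sm.OLS(y, design).fit()
    ssr = float(fit.ssr)
    p = len(retained)
    return QSARModel(
        intercept=float(fit.params[0]),
        coefficients={name: float(c) for name, c in zip(retained, fit.params[1:])},
        n_train=n,
        r2=float(fit.rsquared),
        rmse=math.sqrt(ssr / n),
        s=math.sqrt(ssr / (n - p - 1)),
        training_design=X[retained].to_numpy(dtype=float),
    )


@dataclass(frozen=True)
class CVResult:
    r2_cv: float
    rmsecv: float
    press: float
    r2_cv_sd: float = 0.0
    n_repeats: int = 1


def cross_validate_lto(X: pd.DataFrame, y, fold_size: int = 10,
                       seed: int = 0, n_repeats: int = 1) -> CVResult:
    """Leave-ten-out cross-validation of the full linear model.

    Samples are partitioned into disjoint folds of ``fold_size`` by a seeded
    random permutation (last fold smaller if n is not divisible, with a
    warning); the model is refit on each complement and PRESS accumulates
    the squared held-out residuals.  R2CV = 1 - PRESS/TSS and
    RMSECV = sqrt(PRESS/n).  With ``n_repeats`` > 1 the partition is
    redrawn and the mean statistics (plus the SD of R2CV) are reported.
    """
    X = np.asarray(pd.DataFrame(X), dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= fold_size:
        raise ValueError(f"need n > fold_size, got n={n}, fold_size={fold_size}")
    if n % fold_size:
        warnings.warn(f"n={n} not divisible by fold_size={fold_size}; "
                      "last fold is smaller")
    rng = np.random.default_rng(seed)
    tss = float(np.sum((y - y.mean()) ** 2))
    design = np.column_stack([np.ones(n), X])
    press_list, r2_list, rmsecv_list = [], [], []
    for _ in range(n_repeats):
        order = rng.permutation(n)
        press = 0.0
        for start in range(0, n, fold_size):
            test = order[start:start + fold_size]
            train = np.setdiff1d(order, test)
            beta, *_ = np.linalg.lstsq(design[train], y[train], rcond=None)
            resid = y[test] - design[test] @ beta
            press += float(resid @ resid)
        press_list.append(press)
        r2_list.append(1.0 - press / tss)
        rmsecv_list.append(math.sqrt(press / n))
    return CVResult(r2_cv=float(np.mean(r2_list)),
                    rmsecv=float(np.mean(rmsecv_list)),
                    press=float(np.mean(press_list)),
                    r2_cv_sd=float(np.std(r2_list)),
                    n_repeats=n_repeats)


def applicability_domain(model: QSARModel, query) -> tuple[float, bool]:
    """Leverage of a query point and its in-domain flag.

    h = x (X^T X)^-1 x^T with an intercept column; the query is in-domain
    iff h <= h* = 3 (p + 1) / n (Williams-plot convention).
    """
    if model.training_design is None:
        raise ValueError("model carries no training design; applicability "
                         "domain unavailable")
    X = np.column_stack([np.ones(len(model.training_design)), model.training_design])
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise ValueError("singular X^T X: cannot compute leverage")
    x = np.concatenate([[1.0], model._vector(query)])
    h = float(x @ np.linalg.solve(xtx, x))
    threshold = model.ad_leverage_threshold
    assert threshold is not None
    return h, h <= threshold


def training_leverages(model: QSARModel) -> np.ndarray:
    """Diagonal of the hat matrix over the training rows (sums to p + 1)."""
    if model.training_design is None:
        raise ValueError("model carries no training design")
    X = np.column_stack([np.ones(len(model.training_design)), model.training_design])
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    return np.diag(hat).copy()


# ---------------------------------------------------------------------------
# Table interfaces

def read_descriptor_csv(path) -> pd.DataFrame:
    """Descriptor table (compound/system, logkw, logPcw, E, optional
    logBB_observed); delta_logp is (re)computed, never trusted from file."""
    df = pd.read_csv(path)
    required = {"logkw", "logPcw", "E"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"descriptor CSV missing columns: {missing}")
    df["delta_logp"] = df["logPcw"] - df["logkw"]
    return df
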