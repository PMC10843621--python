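"""Prediction metrics and variable-selection summaries.

R-squared is the general form ``1 - SSE/SST`` with SST taken about the
mean of the evaluation set's true values, so it is valid out-of-sample
(and may be negative there).  RMSE and MAE are the usual root-mean-square
and mean-absolute prediction errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .solvers import CoefficientFit


@dataclass
class EvaluationReport:
    r2: float
    rmse: float
    mae: float
    n: int
    zj: Optional[int] = None
    selected_names: Optional[List[str]] = None

    def to_dict(self) -> dict:
        d = {"r2": self.r2, "rmse": self.rmse, "mae": self.mae, "n": self.n}
        if self.zj is not None:
            d["zj"] = self.zj
        if self.selected_names is not None:
            d["selected"] = list(self.selected_names)
        return d


def _check(y, yhat, min_len=1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 - SSE/SST."""
    y, yhat = _check(y, yhat, min_len=2)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined for constant y")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def count_selected(fit: CoefficientFit, rule: str = "exact_zero",
                   column_names: Optional[List[str]] = None):
    """Number (and names) of variables with exactly nonzero coefficients.

    The solvers produce exact zeros by thresholding, so selection is an
    exact-zero test, not a numerical-tolerance one.
    """
    if rule != "exact_zero":
        raise ValueError(f"unknown selection rule {rule!r}")
    nz = np.flatnonzero(fit.beta)
    names = None
    if column_names is not None:
        names = [column_names[j] for j in nz]
    return int(nz.size), names


def evaluate_predictions(y, yhat, fit: Optional[CoefficientFit] = None,
                         column_names: Optional[List[str]] = None
                         ) -> EvaluationReport:
    """Bundle R^2 / RMSE / MAE (and selection count when a fit is given)."""
    y = np.asarray(y, dtype=float).ravel()
    zj = names = None
    if fit is not None:
        zj, names = count_selected(fit, column_names=column_names)
    return EvaluationReport(r_squared(y, yhat), rmse(y, yhat), mae(y, yhat),
                            int(y.size), zj, names)
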