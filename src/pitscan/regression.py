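"""Linear and exponential strength correlations.

Relates any specimen-level corrosion metric to mechanical strength with the
two standard empirical models, y = m·x + n and y = a·e^{b·x}, each scored by
the coefficient of determination R² = 1 − SSres/SStot. The exponential model
is fitted by nonlinear least squares in the original (untransformed) space —
initialized from the log-linear solution — so both R² values are comparable
in original units; a pure log-space fit would weight small responses more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InputError


@dataclass
class RegressionFit:
    """One fitted model: params = (m, n) for linear, (a, b) for exponential."""

    model: str                  # "linear" | "exponential"
    params: tuple[float, float]
    r2: float
    n_points: int
    p_value: float = float("nan")  # F-test p, linear model only

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            m, n = self.params
            return m * x + n
        a, b = self.params
        return a * np.exp(b * x)


def _validate_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise InputError("need at least 3 points")
    return x, y


def _r2(y, yhat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise FitError("constant response: R2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares y = m·x + n with R² and the slope's p-value."""
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0:
        raise FitError("x values are all equal: slope undefined")
    if np.ptp(y) == 0:
        raise FitError("constant response: R2 undefined")
    res = stats.linregress(x, y)
    fit = RegressionFit(model="linear", params=(float(res.slope), float(res.intercept)),
                        r2=float(res.rvalue**2), n_points=len(x),
                        p_value=float(res.pvalue))
    return fit


def fit_exponential(x, y, maxfev: int = 10000) -> RegressionFit:
    """Nonlinear least squares y = a·e^{b·x}, scored in original space.

    Initialization: the log-linear fit when all y > 0, otherwise a flat curve
    at the mean response (a = ȳ, b = 0).
    """
    x, y = _validate_xy(x, y)
    if np.ptp(y) == 0:
        raise FitError("constant response: R2 undefined")
    if np.ptp(x) == 0:
        raise FitError("x values are all equal: rate unidentifiable")
    if np.all(y > 0):
        b0, loga = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(loga)), float(b0))
    else:
        p0 = (float(y.mean()), 0.0)

    def model(xv, a, b):
        return a * np.exp(np.clip(b * xv, -700, 700))

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=maxfev)
    except RuntimeError as e:
        raise FitError(f"exponential fit did not converge: {e}") from e
    fit = RegressionFit(model="exponential", params=(float(popt[0]), float(popt[1])),
                        r2=_r2(y, model(x, *popt)), n_points=len(x))
    return fit


def correlation_report(metrics_table: pd.DataFrame, strength_column: str) -> pd.DataFrame:
    """Fit both models of every metric column against the strength column.

    Returns one row per (metric, model), ranked by descending R². Columns that
    cannot be fitted (constant values, non-convergence) are kept as flagged
    rows with NaN results rather than aborting the report.
    """
    if strength_column not in metrics_table.columns:
        raise InputError(f"strength column {strength_column!r} not in table")
    if len(metrics_table) < 3:
        raise InputError("need at least 3 specimens")
    y = metrics_table[strength_column].to_numpy(dtype=float)
    rows = []
    for col in metrics_table.columns:
        if col == strength_column:
            continue
        xs = pd.to_numeric(metrics_table[col], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(xs) & np.isfinite(y)
        for name, fitter in (("linear", fit_linear), ("exponential", fit_exponential)):
            row = {"metric": col, "model": name, "param1": np.nan, "param2": np.nan,
                   "r2": np.nan, "p_value": np.nan, "n_points": int(ok.sum()),
                   "flag": ""}
            try:
                if ok.sum() < 3:
                    raise FitError("fewer than 3 finite points")
                fit = fitter(xs[ok], y[ok])
                row.update(param1=fit.params[0], param2=fit.params[1],
                           r2=fit.r2, p_value=fit.p_value)
            except (FitError, InputError) as e:
                row["flag"] = str(e)
            rows.append(row)
    report = pd.DataFrame(rows)
    return report.sort_values("r2", ascending=False, na_position="last",
                              kind="mergesort").reset_index(drop=True)
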