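"""Concentration-response models and the steepness endpoint ``b``.

Two complementary reductions of a response series are provided:

* :func:`fit_log_endpoint` — least squares of ``y = -b ln c + b0`` over
  the non-zero concentrations.  The slope ``b`` (response units per
  ln(mg/kg)) is the derivative of the endpoint with respect to log
  concentration: a concentration-independent summary of the whole
  curve, and the regression target of the descriptor-pruning stage.
* :func:`fit_dose_response` — classical two-parameter sigmoid models
  (logistic, and a threshold variant that is flat up to a no-effect
  concentration) with analytic ECx extraction.

Controls (c = 0) never enter the log fit (ln 0 is undefined); they fix
the control response ``y0`` of the sigmoid models instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from nanoprune.core_data import Material, ResponseSeries

__all__ = [
    "LogEndpointFit",
    "DoseResponseFit",
    "NoConcentrationEffectError",
    "fit_log_endpoint",
    "fit_dose_response",
    "steepness_profile",
]


class NoConcentrationEffectError(RuntimeError):
    """Raised when a series shows no concentration effect to model."""


@dataclass(frozen=True)
class LogEndpointFit:
    """Least-squares fit of y = -b ln c + b0 over non-zero concentrations."""

    b: float
    b0: float
    r_squared: float
    n_points: int

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return -self.b * np.log(c) + self.b0


@dataclass
class DoseResponseFit:
    """Fitted two-parameter sigmoid with analytic ECx.

    logistic2:           y(c) = y0 / (1 + exp(slope * (ln c - ln EC50)))
    threshold_sigmoid2:  y(c) = y0 for c <= t, else 2*y0 / (1 + (c/t)^slope)

    ``y0`` is the control response (fixed from the data, not fitted);
    the two free parameters are (EC50, slope) or (t, slope).
    """

    model: str
    ec50: float
    slope: float
    y0: float
    threshold: float | None = None
    rss: float = float("nan")
    r_squared: float = float("nan")

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.model == "logistic2":
            return _logistic2(c, self.y0, self.ec50, self.slope)
        return _threshold2(c, self.y0, self.threshold, self.slope)

    def ecx(self, x: float) -> float:
        """Concentration causing an x% reduction from the control response."""
        if not 0.0 < x < 100.0:
            raise ValueError("x must be in (0, 100)")
        q = x / 100.0
        if self.model == "logistic2":
            # y0/(1+e^(s(lnc - lnEC50))) = y0(1-q)  =>  c = EC50*(q/(1-q))^(1/s)
            return self.ec50 * math.exp(math.log(q / (1.0 - q)) / self.slope)
        # 2y0/(1+(c/t)^s) = y0(1-q)  =>  c = t*((1+q)/(1-q))^(1/s)
        return self.threshold * ((1.0 + q) / (1.0 - q)) ** (1.0 / self.slope)


def _logistic2(c, y0, ec50, slope):
    with np.errstate(over="ignore", divide="ignore"):
        z = slope * (np.log(c) - np.log(ec50))
        return y0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def _threshold2(c, y0, t, slope):
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, y0, dtype=float)
    above = c > t
    with np.errstate(over="ignore"):
        ratio = np.power(c[above] / t, slope)
    out[above] = 2.0 * y0 / (1.0 + ratio)
    return out


def fit_log_endpoint(series: ResponseSeries, weighted: bool = True) -> LogEndpointFit:
    """Fit y = -b ln c + b0 by (optionally weighted) least squares.

    Controls are excluded; at least 3 distinct non-zero concentrations
    are required.  Replicate weights 1/sd^2 are applied only when every
    point carries a positive sd, otherwise the fit is unweighted.  A
    flat series returns b = 0 with R^2 reported as 0.
    """
    nz = series.nonzero()
    if len(np.unique(nz.concentrations)) < 3:
        raise ValueError(
            f"need >=3 distinct non-zero concentrations, got {len(nz.concentrations)}"
        )
    x = np.log(nz.concentrations)
    y = nz.mean
    if weighted and np.all(np.isfinite(nz.sd)) and np.all(nz.sd > 0):
        w = 1.0 / nz.sd**2
    else:
        w = np.ones_like(y)

    # weighted normal equations for y = a*x + b0 with a = -b
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate series: all concentrations equal")
    a = (w * (x - xbar) * (y - ybar)).sum() / sxx
    b0 = ybar - a * xbar
    b = -a

    resid = y - (a * x + b0)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LogEndpointFit(b=float(b), b0=float(b0), r_squared=float(r2), n_points=len(y))


def fit_dose_response(
    series: ResponseSeries,
    model: str = "logistic2",
    n_starts: int = 8,
    rel_tol_flat: float = 1e-9,
) -> DoseResponseFit:
    """Fit a two-parameter sigmoid to a response series including its control.

    The control mean fixes ``y0``; (EC50, slope) — or (t, slope) for the
    threshold model — minimise the residual sum of squares, weighted by
    1/sd^2 when every point has a positive sd.  A multistart over a
    log-spaced EC50/threshold grid makes the solution deterministic and
    robust; a series with no concentration effect raises
    :class:`NoConcentrationEffectError`.
    """
    if model not in ("logistic2", "threshold_sigmoid2"):
        raise ValueError(f"unknown model {model!r}")
    if len(series.concentrations) < 4 or series.concentrations[0] != 0:
        raise ValueError("need >=4 points including the control (concentration 0)")
    if np.any(series.mean < 0):
        raise ValueError("responses must be non-negative")

    y0 = float(series.mean[series.concentrations == 0].mean())
    nz = series.nonzero()
    c, y = nz.concentrations, nz.mean
    if weighted := (np.all(np.isfinite(nz.sd)) and np.all(nz.sd > 0)):
        w = 1.0 / nz.sd**2
    else:
        w = np.ones_like(y)
    sqrtw = np.sqrt(w)

    span = float(np.max(series.mean) - np.min(series.mean))
    if span <= rel_tol_flat * max(1.0, float(np.max(series.mean))):
        raise NoConcentrationEffectError(
            f"{series.material} day {series.day} {series.endpoint}: "
            "no concentration effect; EC50 undefined"
        )
    rho = pd.Series(y).corr(pd.Series(np.log(c)), method="spearman")
    if rho is not None and rho > 0:
        warnings.warn(
            f"{series.material}: response increases with concentration; "
            "fit returned but ECx may be meaningless",
            stacklevel=2,
        )

    lo, hi = float(c.min()), float(c.max())
    grid = np.exp(np.linspace(math.log(lo / 3.0), math.log(hi * 3.0), n_starts))

    if model == "logistic2":

        def make_resid(_):
            def resid(p):
                ec50, slope = np.exp(p[0]), p[1]
                return sqrtw * (_logistic2(c, y0, ec50, slope) - y)

            return resid

        best = None
        for start_ec50 in grid:
            for start_slope in (1.0, 3.0):
                sol = least_squares(
                    make_resid(None),
                    x0=[math.log(start_ec50), start_slope],
                    bounds=([math.log(lo) - 10, 1e-6], [math.log(hi) + 10, 100.0]),
                    method="trf",
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("logistic2 fit did not converge after multistart")
        ec50, slope = float(np.exp(best.x[0])), float(best.x[1])
        fit = DoseResponseFit(model=model, ec50=ec50, slope=slope, y0=y0)
    else:
        # profile the threshold over a grid of candidate t values; ties
        # broken toward smaller t
        t_grid = np.exp(np.linspace(math.log(lo / 2.0), math.log(hi), 64))
        best_t, best_cost, best_slope = None, np.inf, None
        for t in t_grid:
            def resid(p, t=t):
                return sqrtw * (_threshold2(c, y0, t, p[0]) - y)

            sol = least_squares(resid, x0=[2.0], bounds=([1e-6], [100.0]), method="trf")
            if best_t is None or sol.cost < best_cost - 1e-12 * max(best_cost, 1.0):
                best_t, best_cost, best_slope = float(t), sol.cost, float(sol.x[0])
        if best_t is None:
            raise RuntimeError("threshold_sigmoid2 fit did not converge")
        fit = DoseResponseFit(
            model=model,
            ec50=float("nan"),
            slope=best_slope,
            y0=y0,
            threshold=best_t,
        )
        fit.ec50 = fit.ecx(50.0)

    pred = fit.predict(c)
    fit.rss = float((w * (pred - y) ** 2).sum())
    ybar = (w * y).sum() / w.sum()
    ss_tot = float((w * (y - ybar) ** 2).sum())
    fit.r_squared = 1.0 - fit.rss / ss_tot if ss_tot > 0 else 0.0
    return fit


def steepness_profile(
    fits: dict[Material, "LogEndpointFit | dict[int, LogEndpointFit]"],
) -> pd.DataFrame:
    """Tabulate the steepness endpoint b against Fe doping.

    ``fits`` maps each :class:`Material` either to a single fit or to a
    ``{day: fit}`` mapping.  Returns a DataFrame with columns
    (material, fe_fraction, day, b, b0, r_squared) sorted by
    fe_fraction — ready for trend tests of b against Fe%.
    """
    rows = []
    for mat, val in fits.items():
        per_day = val if isinstance(val, dict) else {None: val}
        for day, fit in per_day.items():
            rows.append(
                {
                    "material": mat.name,
                    "fe_fraction": mat.fe_fraction,
                    "day": day,
                    "b": fit.b,
                    "b0": fit.b0,
                    "r_squared": fit.r_squared,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["fe_fraction", "material", "day"], kind="stable")
        .reset_index(drop=True)
    )
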