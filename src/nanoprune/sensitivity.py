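"""Final response fit and per-descriptor sensitivity / directionality.

After pruning, the raw biological response (not the b endpoint) is
refitted on the final descriptor set — the pruning survivors plus the
concentration-dependent parameters (concentration, hydrodynamic size,
zeta potential).  Each descriptor is then swept from its observed
minimum to maximum while the remaining descriptors are held at the
values of each data row, for every model on the Pareto front.  Each
(model, row) case is classified as a positive, negative or flat
response by the rank correlation of the model output with the sweep
grid (cutoffs +-0.5); `sensitivity` is the average swept output range
relative to the model's output spread, rescaled so the most
influential descriptor of each day scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from nanoprune.symbolic import (
    FrontModel,
    ParetoFront,
    RegressorConfig,
    canonical_configs,
    evolve,
    normalize,
    pareto_filter,
)

__all__ = ["SensitivityReport", "final_fit", "sensitivity_scan", "sensitivity_report"]

MONOTONE_RHO_CUTOFF = 0.5


@dataclass
class SensitivityReport:
    """Per-descriptor sensitivity and directionality for one exposure day."""

    day: int | None
    table: pd.DataFrame  # index descriptor; sensitivity, pct_positive, pct_negative, pct_none
    best_r_squared: float
    n_models: int

    def ranked(self) -> list[str]:
        return self.table.sort_values("sensitivity", ascending=False).index.tolist()


def final_fit(
    m: pd.DataFrame,
    y: np.ndarray | pd.Series,
    seed: int = 0,
    configs: list[RegressorConfig] | None = None,
    min_accuracy: float = 0.5,
    **overrides,
) -> ParetoFront:
    """Symbolic fit of the raw response on the final descriptor set.

    Runs the six canonical configurations (unless explicit ``configs``
    are given) on z-scored data and merges their fronts into one.  A
    constant response yields the constant model with R^2 reported as 0
    and a warning.  ``min_accuracy`` drops the low-accuracy tail of the
    merged front so the sensitivity scan only considers models that
    actually describe the data.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant response: R^2 reported as 0", stacklevel=2)
    X_norm, _ = normalize(m)
    sd = y.std(ddof=1)
    y_norm = (y - y.mean()) / sd if sd > 0 else y - y.mean()
    if configs is None:
        configs = canonical_configs(seed=seed, **overrides)
    models: list[FrontModel] = []
    names = list(m.columns)
    for cfg in configs:
        front = evolve(X_norm, y_norm, cfg)
        models.extend(front.models)
    merged = pareto_filter(models, variable_names=names)
    kept = [mm for mm in merged.models if mm.r_squared >= min_accuracy or mm.complexity <= 1]
    if not kept:
        kept = merged.models
    return ParetoFront(models=kept, variable_names=names)


def sensitivity_scan(
    front: ParetoFront,
    m: pd.DataFrame,
    descriptor: str,
    n_grid: int = 21,
) -> tuple[float, float, float, float]:
    """Sweep one descriptor over its observed range for every (model, row).

    Returns (sensitivity, pct_positive, pct_negative, pct_none);
    percentages sum to 100.  The sensitivity returned here is the raw
    (unrescaled) mean |output range| / output sd; per-day rescaling to
    a maximum of 1 happens in :func:`sensitivity_report`.
    """
    if not front.models:
        raise ValueError("empty front")
    names = front.variable_names
    j = names.index(descriptor)
    X = m[names].to_numpy(dtype=float)
    lo, hi = float(X[:, j].min()), float(X[:, j].max())
    if lo == hi:
        return 0.0, 0.0, 0.0, 100.0
    grid = np.linspace(lo, hi, n_grid)

    n_pos = n_neg = n_none = 0
    impacts: list[float] = []
    for model in front.models:
        if model.expression is None:
            continue
        preds = model.predict(X)
        out_sd = float(np.std(preds))
        uses = j in model.variables()
        for row in X:
            if not uses:
                n_none += 1
                impacts.append(0.0)
                continue
            sweep = np.tile(row, (n_grid, 1))
            sweep[:, j] = grid
            out = model.predict(sweep)
            if np.ptp(out) == 0:
                rho = 0.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, _ = spearmanr(grid, out)
                rho = 0.0 if not np.isfinite(rho) else float(rho)
            if rho > MONOTONE_RHO_CUTOFF:
                n_pos += 1
            elif rho < -MONOTONE_RHO_CUTOFF:
                n_neg += 1
            else:
                n_none += 1
            impacts.append(float(np.ptp(out)) / out_sd if out_sd > 0 else 0.0)
    n_cases = n_pos + n_neg + n_none
    if n_cases == 0:
        return 0.0, 0.0, 0.0, 100.0
    sens = float(np.mean(impacts))
    return (
        sens,
        100.0 * n_pos / n_cases,
        100.0 * n_neg / n_cases,
        100.0 * n_none / n_cases,
    )


def sensitivity_report(
    front: ParetoFront,
    m: pd.DataFrame,
    day: int | None = None,
    n_grid: int = 21,
) -> SensitivityReport:
    """Scan every descriptor and rescale sensitivities to max 1 for the day."""
    rows = {}
    for name in front.variable_names:
        s, p, n, z = sensitivity_scan(front, m, name, n_grid=n_grid)
        rows[name] = {
            "sensitivity": s,
            "pct_positive": p,
            "pct_negative": n,
            "pct_none": z,
        }
    table = pd.DataFrame(rows).T
    peak = table["sensitivity"].max()
    if peak > 0:
        table["sensitivity"] = table["sensitivity"] / peak
    best_r2 = max((mm.r_squared for mm in front.models), default=float("nan"))
    return SensitivityReport(
        day=day, table=table, best_r_squared=float(best_r2), n_models=len(front.models)
    )
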