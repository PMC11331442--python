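"""Iterative descriptor pruning against the steepness endpoint ``b``.

Each round runs the six canonical symbolic-regression configurations
(2 building-block sets x 3 metrics) on the surviving candidates,
averages the accuracy-weighted Pareto-front occurrence of each
variable into a weighted importance, keeps the best-ranked 40%
(ceiling), and stops when the mean/sd ratio of the survivors'
importances drops below 0.2 or at most 3 variables remain.

The stopping inequality is applied literally (stop when ratio < 0.2):
a low mean/sd means the surviving importances are strongly dispersed,
i.e. a few variables dominate and further pruning would only shave the
established tail.  The converse reading (prune while the ratio is
high) appears in some protocol descriptions; the hard floor of 3
variables guarantees termination under either convention, and the
trace records the ratio at every round so the call can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanoprune.symbolic import (
    RegressorConfig,
    canonical_configs,
    evolve,
    normalize,
    variable_occurrence,
)

__all__ = ["PruningRound", "PruningTrace", "importance_ratio", "run_pruning"]

RATIO_INFINITY = float("inf")


@dataclass
class PruningRound:
    index: int
    candidates: list[str]
    importance: dict[str, float]
    survivors: list[str]
    stop_ratio: float


@dataclass
class PruningTrace:
    rounds: list[PruningRound] = field(default_factory=list)
    final_descriptors: list[str] = field(default_factory=list)
    terminated_reason: str = ""  # "ratio_criterion" | "min_variables"

    def importance_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rounds:
            for name, imp in sorted(r.importance.items()):
                rows.append(
                    {"round": r.index, "variable": name, "importance": imp,
                     "survived": name in r.survivors}
                )
        return pd.DataFrame(rows)


def importance_ratio(importances) -> float:
    """mean / sd (n-1) of a set of importances; +inf when sd == 0."""
    arr = np.asarray(list(importances), dtype=float)
    if arr.size < 2:
        raise ValueError("need >=2 importance values")
    sd = arr.std(ddof=1)
    if sd == 0:
        return RATIO_INFINITY
    return float(arr.mean() / sd)


def run_pruning(
    b_table: pd.Series,
    candidates: pd.DataFrame,
    seed: int = 0,
    keep_fraction: float = 0.4,
    stop_ratio: float = 0.2,
    min_variables: int = 3,
    max_rounds: int = 20,
    regressor_overrides: dict | None = None,
) -> PruningTrace:
    """Prune candidate descriptors against per-material b values.

    Parameters
    ----------
    b_table
        One steepness value b per material (index = material name).
    candidates
        Per-material values of the candidate descriptors (cluster
        representatives, concentration-independent), indexed like
        ``b_table``.
    seed
        Master seed; every (round, configuration) gets a distinct
        derived sub-seed.
    regressor_overrides
        Optional RegressorConfig overrides applied to all six canonical
        configurations.  When omitted, a pruning-scale budget is used
        (population 200, 40 generations, stall cutoff 15): each round
        runs six regressions on a handful of materials, where this
        budget recovers planted low-complexity relations reliably while
        keeping a full multi-round trace fast.

    Returns the full per-round trace, ending either on the
    ratio criterion or on the ``min_variables`` floor.
    """
    # canonical column order: results are invariant to how the caller
    # happened to order the candidate columns
    candidates = candidates.loc[b_table.index, sorted(candidates.columns)]
    names = list(candidates.columns)
    if len(names) < 2:
        raise ValueError("need >=2 candidate descriptors")

    # normalize predictors and target once; b is the regression target
    X_norm, _ = normalize(candidates)
    y = b_table.to_numpy(dtype=float)
    y_norm = (y - y.mean()) / y.std(ddof=1) if y.std(ddof=1) > 0 else y - y.mean()

    overrides = dict(population=200, generations=40, stall_generations=15)
    overrides.update(regressor_overrides or {})
    trace = PruningTrace()
    current = names
    for round_idx in range(1, max_rounds + 1):
        configs = canonical_configs(seed=(seed * 1009 + round_idx) % 2**31, **overrides)
        importance = _round_importance(X_norm[sorted(current)], y_norm, configs)

        order = sorted(current, key=lambda n: (-importance[n], n))
        # ceil(40%) retention, but never below the termination floor
        n_keep = min(len(current), max(min_variables, math.ceil(keep_fraction * len(current))))
        cutoff = importance[order[n_keep - 1]]
        # ties at the cutoff: keep all tied, then trim from the
        # lexicographically last of the lowest-importance survivors
        survivors = [n for n in order if importance[n] > cutoff]
        tied = sorted(n for n in current if importance[n] == cutoff)
        survivors += tied[: max(0, n_keep - len(survivors))]
        survivors = sorted(survivors, key=lambda n: order.index(n))

        ratio = importance_ratio([importance[n] for n in survivors]) if len(survivors) > 1 else RATIO_INFINITY
        trace.rounds.append(
            PruningRound(
                index=round_idx,
                candidates=list(current),
                importance=importance,
                survivors=survivors,
                stop_ratio=ratio,
            )
        )
        no_shrink = len(survivors) == len(trace.rounds[-1].candidates)
        current = survivors
        if ratio < stop_ratio:
            trace.terminated_reason = "ratio_criterion"
            break
        if len(current) <= min_variables or no_shrink:
            trace.terminated_reason = "min_variables"
            break
    else:
        trace.terminated_reason = "min_variables"

    trace.final_descriptors = list(current)
    return trace


def _round_importance(
    X: pd.DataFrame, y: np.ndarray, configs: list[RegressorConfig]
) -> dict[str, float]:
    """Average accuracy-weighted front occurrence over the configurations."""
    total = {name: 0.0 for name in X.columns}
    for cfg in configs:
        front = evolve(X, y, cfg)
        occ = variable_occurrence(front)
        for name in total:
            total[name] += occ.get(name, 0.0)
    return {name: v / len(configs) for name, v in total.items()}
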