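"""The genetic-programming loop, Pareto filtering and occurrence counts.

Model accuracy is always computed after linear output scaling
(pred = a + b * f(x), with a, b from ordinary least squares): the GP
only has to discover the functional shape, while scale and offset are
absorbed analytically.  Three fitness metrics are available:

* ``r_square`` — coefficient of determination of the scaled prediction;
* ``absolute_error`` — 1 - MAE / MAE of the constant-mean baseline;
* ``hybrid`` — arithmetic mean of the two.

All metrics are "higher is better" scores in [0, 1], so a single
Pareto-front convention (complexity down, accuracy up) serves all six
canonical configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from nanoprune.symbolic.expression import BLOCK_SETS, OPS, Expression

__all__ = [
    "RegressorConfig",
    "FrontModel",
    "ParetoFront",
    "NormalizationState",
    "normalize",
    "evolve",
    "pareto_filter",
    "variable_occurrence",
    "canonical_configs",
]

METRICS = ("r_square", "absolute_error", "hybrid")


@dataclass(frozen=True)
class RegressorConfig:
    """Settings for one symbolic-regression run.

    The population/generation defaults are a desk-scale budget chosen
    so that planted low-complexity relations on tens of rows are
    recovered in seconds; both are plain configuration, not part of any
    contract.
    """

    building_blocks: str = "rational_polynomial"
    metric: str = "r_square"
    population: int = 500
    generations: int = 200
    seed: int = 0
    tournament_size: int = 5
    p_crossover: float = 0.65
    p_subtree_mutation: float = 0.15
    p_point_mutation: float = 0.10
    p_constant_jitter: float = 0.05
    max_nodes: int = 25
    init_max_depth: int = 3
    const_range: tuple[float, float] = (-2.0, 2.0)
    refine_constants: bool = True
    early_stop_score: float = 1.0 - 1e-6
    stall_generations: int = 40

    def __post_init__(self):
        if self.building_blocks not in BLOCK_SETS:
            raise ValueError(f"unknown building_blocks {self.building_blocks!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


def canonical_configs(seed: int = 0, **overrides) -> list[RegressorConfig]:
    """The six canonical configurations: 2 block sets x 3 metrics.

    Each gets a distinct sub-seed derived from ``seed`` so runs are
    independent but reproducible.
    """
    configs = []
    for i, blocks in enumerate(BLOCK_SETS):
        for j, metric in enumerate(METRICS):
            configs.append(
                RegressorConfig(
                    building_blocks=blocks,
                    metric=metric,
                    seed=(seed * 6 + i * 3 + j) % (2**31 - 1),
                    **overrides,
                )
            )
    return configs


@dataclass
class FrontModel:
    expression: Expression | None
    complexity: int
    accuracy: float
    r_squared: float = float("nan")
    mae: float = float("nan")
    scale: tuple[float, float] = (0.0, 1.0)  # (a, b) of pred = a + b*f

    def expression_str(self, names: list[str] | None = None) -> str:
        if self.expression is None:
            return ""
        a, b = self.scale
        return f"{a:.6g} + {b:.6g}*({self.expression.to_str(names)})"

    def predict(self, X: np.ndarray) -> np.ndarray:
        a, b = self.scale
        return a + b * self.expression.eval(X)

    def variables(self) -> set[int]:
        return self.expression.variables() if self.expression is not None else set()


@dataclass
class ParetoFront:
    """Non-dominated models in (complexity down, accuracy up), sorted by complexity."""

    models: list[FrontModel]
    variable_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def best(self) -> FrontModel:
        if not self.models:
            raise ValueError("empty front")
        return max(self.models, key=lambda m: (m.accuracy, -m.complexity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "complexity": [m.complexity for m in self.models],
                "accuracy": [m.accuracy for m in self.models],
                "r_squared": [m.r_squared for m in self.models],
                "mae": [m.mae for m in self.models],
                "expression": [m.expression_str(self.variable_names) for m in self.models],
            }
        )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationState:
    mean: pd.Series
    sd: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.mean.index] - self.mean) / self.sd

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[self.mean.index] * self.sd + self.mean


def normalize(df: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationState]:
    """Z-score every column (n-1 sd); raises naming any zero-variance column."""
    if len(df) < 2:
        raise ValueError("need >=2 rows to normalize")
    sd = df.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns cannot be normalized: {zero}")
    state = NormalizationState(mean=df.mean(), sd=sd)
    return state.transform(df), state


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def _linear_scale(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = f.shape[0]
    fm = f.sum() / n
    ym = y.sum() / n
    fc = f - fm
    var_f = fc @ fc
    if not np.isfinite(var_f) or var_f < 1e-18 * n:
        return float(ym), 0.0
    b = float((fc @ (y - ym)) / var_f)
    return float(ym - b * fm), b


def _score(f: np.ndarray, y: np.ndarray, mae0: float, ss_tot: float, metric: str):
    """Return (score, r2, mae, (a, b)) for raw model output f."""
    if not np.all(np.isfinite(f)):
        return 0.0, 0.0, float("inf"), (0.0, 0.0)
    a, b = _linear_scale(f, y)
    pred = a + b * f
    resid = pred - y
    ss_res = float(resid @ resid)
    r2 = max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    mae = float(np.abs(resid).mean())
    inv_err = max(0.0, 1.0 - mae / mae0) if mae0 > 0 else 0.0
    if metric == "r_square":
        score = r2
    elif metric == "absolute_error":
        score = inv_err
    else:  # hybrid correlation/error index
        score = 0.5 * r2 + 0.5 * inv_err
    return score, r2, mae, (a, b)


# ---------------------------------------------------------------------------
# GP operators
# ---------------------------------------------------------------------------


def _random_terminal(rng, n_vars, const_range):
    if rng.random() < 0.8:
        return Expression.variable(int(rng.integers(n_vars)))
    return Expression.constant(rng.uniform(*const_range))


def _random_tree(rng, n_vars, ops, depth, const_range, full):
    if depth <= 0 or (not full and rng.random() < 0.3):
        return _random_terminal(rng, n_vars, const_range)
    op = ops[int(rng.integers(len(ops)))]
    arity = OPS[op][0]
    children = [
        _random_tree(rng, n_vars, ops, depth - 1, const_range, full)
        for _ in range(arity)
    ]
    return Expression(op, children)


def _pick_node(rng, expr: Expression) -> tuple[Expression | None, int]:
    """Pick a node uniformly; returns (parent, child-index); parent None = root."""
    nodes = []

    def walk(node, parent, idx):
        nodes.append((parent, idx, node))
        for i, c in enumerate(node.children):
            walk(c, node, i)

    walk(expr, None, -1)
    parent, idx, _ = nodes[int(rng.integers(len(nodes)))]
    return parent, idx


def _crossover(rng, a: Expression, b: Expression, max_nodes: int) -> Expression:
    child = a.clone()
    pa, ia = _pick_node(rng, child)
    donor_parent, ib = _pick_node(rng, b)
    donor = (b if donor_parent is None else donor_parent.children[ib]).clone()
    if pa is None:
        child = donor
    else:
        pa.children[ia] = donor
    return child if child.complexity <= max_nodes else a.clone()


def _subtree_mutation(rng, a, n_vars, ops, const_range, max_nodes):
    child = a.clone()
    pa, ia = _pick_node(rng, child)
    new = _random_tree(rng, n_vars, ops, 2, const_range, full=False)
    if pa is None:
        child = new
    else:
        pa.children[ia] = new
    return child if child.complexity <= max_nodes else a.clone()


def _point_mutation(rng, a, n_vars, ops, const_range):
    child = a.clone()
    for node in child.nodes():
        if rng.random() >= 0.15:
            continue
        if node.op == "var":
            node.var = int(rng.integers(n_vars))
        elif node.op == "const":
            node.value = float(node.value + rng.normal(0, 0.5))
        else:
            arity = OPS[node.op][0]
            same = [o for o in ops if OPS[o][0] == arity]
            node.op = same[int(rng.integers(len(same)))]
    return child


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def evolve(
    data: pd.DataFrame,
    target: str | np.ndarray,
    cfg: RegressorConfig,
) -> ParetoFront:
    """Evolve a Pareto front of expressions predicting ``target`` from ``data``.

    ``data`` holds the (typically pre-normalized) predictors; ``target``
    is either a column name within ``data`` or an explicit vector.
    Deterministic for a fixed config (including its seed).
    """
    if isinstance(target, str):
        y = data[target].to_numpy(dtype=float)
        X_df = data.drop(columns=[target])
    else:
        y = np.asarray(target, dtype=float)
        X_df = data
    if X_df.shape[1] < 1:
        raise ValueError("need at least one predictor")
    if len(y) != len(X_df):
        raise ValueError("target length must match data rows")
    names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    n_vars = X.shape[1]

    # degenerate target: the constant model is exact and minimal
    if np.ptp(y) == 0:
        const = FrontModel(
            expression=Expression.constant(float(y[0]) if len(y) else 0.0),
            complexity=1,
            accuracy=1.0,
            r_squared=0.0,
            mae=0.0,
            scale=(0.0, 1.0),
        )
        return ParetoFront(models=[const], variable_names=names)

    rng = np.random.default_rng(cfg.seed)
    ops = BLOCK_SETS[cfg.building_blocks]
    mae0 = float(np.abs(y - y.mean()).mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())

    # archive: best (score, expr, r2, mae, scale) per complexity
    archive: dict[int, tuple[float, Expression, float, float, tuple]] = {}

    def evaluate(expr: Expression) -> tuple[float, int]:
        with np.errstate(all="ignore"):
            f = expr.eval(X)
        score, r2, mae, scale = _score(f, y, mae0, ss_tot, cfg.metric)
        comp = expr.complexity
        prev = archive.get(comp)
        if prev is None or score > prev[0] + 1e-12:
            archive[comp] = (score, expr.clone(), r2, mae, scale)
        return score, comp

    # ramped half-and-half init, plus every bare variable
    pop: list[Expression] = [Expression.variable(i) for i in range(n_vars)]
    depths = list(range(1, cfg.init_max_depth + 1))
    while len(pop) < cfg.population:
        d = depths[len(pop) % len(depths)]
        full = (len(pop) // len(depths)) % 2 == 0
        pop.append(_random_tree(rng, n_vars, ops, d, cfg.const_range, full))
    pop = pop[: max(cfg.population, n_vars)]
    evals = [evaluate(e) for e in pop]
    scores = np.array([s for s, _ in evals])
    comps = np.array([c for _, c in evals])

    best_score = float(scores.max())
    stall = 0
    for _ in range(cfg.generations):
        if best_score >= cfg.early_stop_score or stall >= cfg.stall_generations:
            break
        new_pop: list[Expression] = []
        # elitism: keep the single best individual
        new_pop.append(pop[int(np.argmax(scores))].clone())
        n = len(pop)
        while len(new_pop) < n:
            r = rng.random()
            parent = _tournament(rng, pop, scores, comps, cfg.tournament_size)
            if r < cfg.p_crossover:
                donor = _tournament(rng, pop, scores, comps, cfg.tournament_size)
                child = _crossover(rng, parent, donor, cfg.max_nodes)
            elif r < cfg.p_crossover + cfg.p_subtree_mutation:
                child = _subtree_mutation(
                    rng, parent, n_vars, ops, cfg.const_range, cfg.max_nodes
                )
            elif r < cfg.p_crossover + cfg.p_subtree_mutation + cfg.p_point_mutation:
                child = _point_mutation(rng, parent, n_vars, ops, cfg.const_range)
            else:
                child = parent.clone()
                for cn in child.constant_nodes():
                    cn.value = float(cn.value + rng.normal(0, 0.1))
            new_pop.append(child)
        pop = new_pop
        evals = [evaluate(e) for e in pop]
        scores = np.array([s for s, _ in evals])
        comps = np.array([c for _, c in evals])
        gen_best = float(scores.max())
        if gen_best > best_score + 1e-12:
            best_score = gen_best
            stall = 0
        else:
            stall += 1

    if not archive:
        raise RuntimeError("generation budget exhausted with no finite-accuracy model")

    models = [
        FrontModel(expression=e, complexity=comp, accuracy=s, r_squared=r2, mae=mae, scale=sc)
        for comp, (s, e, r2, mae, sc) in sorted(archive.items())
    ]
    front = pareto_filter(models, variable_names=names)
    if cfg.refine_constants:
        front = _refine_front(front, X, y, mae0, ss_tot, cfg.metric)
    return front


def _tournament(rng, pop, scores, comps, k) -> Expression:
    idx = rng.integers(len(pop), size=k)
    sub = scores[idx]
    best = sub.max()
    # parsimony tie-break: among near-equal scores prefer the smaller tree
    cand = [int(i) for i, s in zip(idx, sub) if s >= best - 1e-9]
    return pop[min(cand, key=lambda i: comps[i])]


def _refine_front(front: ParetoFront, X, y, mae0, ss_tot, metric) -> ParetoFront:
    """Polish the constants of each front model by local least squares."""
    refined = []
    for m in front.models:
        expr = m.expression
        consts = expr.constant_nodes()
        if consts:
            expr = expr.clone()
            consts = expr.constant_nodes()
            x0 = np.array([c.value for c in consts])

            def resid(p, expr=expr, consts=consts):
                for c, v in zip(consts, p):
                    c.value = float(v)
                f = expr.eval(X)
                a, b = _linear_scale(f, y)
                return a + b * f - y

            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=60)
                for c, v in zip(consts, sol.x):
                    c.value = float(v)
            except Exception:
                for c, v in zip(consts, x0):
                    c.value = float(v)
        score, r2, mae, scale = _score(expr.eval(X), y, mae0, ss_tot, metric)
        if score >= m.accuracy:
            refined.append(
                FrontModel(expr, m.complexity, score, r2, mae, scale)
            )
        else:
            refined.append(m)
    return pareto_filter(refined, variable_names=front.variable_names)


def pareto_filter(models, variable_names: list[str] | None = None) -> ParetoFront:
    """Exact non-dominated filtering in (complexity down, accuracy up).

    Accepts FrontModel instances or bare (complexity, accuracy) tuples.
    Equal-complexity ties keep only the higher accuracy; duplicates are
    removed.  Empty input yields an empty front.
    """
    items: list[FrontModel] = []
    for m in models:
        if isinstance(m, FrontModel):
            items.append(m)
        else:
            comp, acc = m
            items.append(FrontModel(expression=None, complexity=int(comp), accuracy=float(acc)))
    for m in items:
        if not math.isfinite(m.accuracy):
            raise ValueError("accuracies must be finite")

    items.sort(key=lambda m: (m.complexity, -m.accuracy))
    kept: list[FrontModel] = []
    best_acc = -math.inf
    last_comp = None
    for m in items:
        if m.complexity == last_comp:
            continue  # lower-accuracy tie at same complexity
        if m.accuracy > best_acc:
            kept.append(m)
            best_acc = m.accuracy
            last_comp = m.complexity
        else:
            last_comp = m.complexity
    return ParetoFront(models=kept, variable_names=variable_names or [])


def variable_occurrence(front: ParetoFront) -> dict[str, float]:
    """Accuracy-weighted occurrence of each variable across front models.

    Model weights are the (non-negative) accuracies normalized to sum 1
    over the front; a variable scores the total weight of the models it
    appears in.
    """
    if not front.models:
        raise ValueError("empty front")
    names = front.variable_names
    acc = np.array([max(0.0, m.accuracy) for m in front.models])
    weights = acc / acc.sum() if acc.sum() > 0 else np.full(len(acc), 1.0 / len(acc))
    occ = {name: 0.0 for name in (names if names else [])}
    for m, w in zip(front.models, weights):
        for vi in m.variables():
            key = names[vi] if names else f"x{vi}"
            occ[key] = occ.get(key, 0.0) + float(w)
    return occ
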