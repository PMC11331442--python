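import itertools

import numpy as np
import pandas as pd
import pytest

from nanoprune.symbolic import (
    Expression,
    FrontModel,
    RegressorConfig,
    canonical_configs,
    evolve,
    normalize,
    pareto_filter,
    variable_occurrence,
)
from nanoprune.symbolic.expression import BLOCK_SETS, OPS


class TestNormalize:
    def test_z_scores_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, state = normalize(df)
        assert np.allclose(out["a"], [-1, 0, 1])

    def test_idempotent_on_normalized_data(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        once, _ = normalize(df)
        twice, _ = normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 3, size=(10, 2)), columns=["x", "y"])
        out, state = normalize(df)
        back = state.inverse(out)
        assert np.allclose(back.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            normalize(df)


class TestExpression:
    def test_guarded_operators_stay_finite(self):
        X = np.array([[0.0], [-1.0], [1e-12], [5.0], [-200.0]])
        x = Expression.variable(0)
        exprs = [
            Expression("div", [Expression.constant(1.0), x]),
            Expression("log", [x]),
            Expression("sqrt", [x]),
            Expression("exp", [x]),
            Expression("div", [x, Expression("log", [x])]),
        ]
        for e in exprs:
            assert np.all(np.isfinite(e.eval(X)))

    def test_complexity_is_node_count(self):
        e = Expression("add", [Expression.variable(0),
                               Expression("mul", [Expression.constant(2.0),
                                                  Expression.variable(1)])])
        assert e.complexity == 5

    def test_string_round_trip_stability(self):
        e = Expression("sub", [Expression.variable(1), Expression.constant(0.5)])
        assert e.to_str(["a", "b"]) == "(b - 0.5)"
        assert e.clone() == e


def brute_force_front(models):
    """Independent dominance oracle: pairwise comparison."""
    out = []
    for i, (ci, ai) in enumerate(models):
        dominated = any(
            (cj <= ci and aj >= ai) and (cj < ci or aj > ai)
            for j, (cj, aj) in enumerate(models)
            if j != i
        )
        duplicate = any(
            (cj, aj) == (ci, ai) for j, (cj, aj) in enumerate(models[:i])
        )
        if not dominated and not duplicate:
            out.append((ci, ai))
    return sorted(out)


class TestParetoFilter:
    def test_hand_example(self):
        front = pareto_filter([(3, 0.90), (5, 0.95), (4, 0.85)])
        assert [(m.complexity, m.accuracy) for m in front.models] == [(3, 0.90), (5, 0.95)]

    def test_single_model(self):
        front = pareto_filter([(7, 0.5)])
        assert [(m.complexity, m.accuracy) for m in front.models] == [(7, 0.5)]

    def test_duplicates_removed(self):
        front = pareto_filter([(3, 0.9), (3, 0.9), (3, 0.8)])
        assert [(m.complexity, m.accuracy) for m in front.models] == [(3, 0.9)]

    def test_empty_input(self):
        assert len(pareto_filter([])) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(1, 50)
            models = [
                (int(rng.integers(1, 20)), float(np.round(rng.random(), 3)))
                for _ in range(n)
            ]
            got = sorted((m.complexity, m.accuracy) for m in pareto_filter(models).models)
            assert got == brute_force_front(models)


class TestVariableOccurrence:
    def front(self, specs):
        models = []
        for expr, acc in specs:
            models.append(FrontModel(expression=expr, complexity=expr.complexity, accuracy=acc))
        return pareto_filter(models, variable_names=["x1", "x2", "x3"])

    def test_weighted_occurrence_hand_example(self):
        x1, x2 = Expression.variable(0), Expression.variable(1)
        m1 = Expression("add", [x1.clone(), x2.clone()])  # uses x1, x2
        m2 = Expression("mul", [x1.clone(), x1.clone()])  # uses x1
        front = pareto_filter(
            [FrontModel(m1, 5, 0.6), FrontModel(m2, 3, 0.4)],
            variable_names=["x1", "x2", "x3"],
        )
        occ = variable_occurrence(front)
        assert occ["x1"] == pytest.approx(1.0)
        assert occ["x2"] == pytest.approx(0.6)
        assert occ["x3"] == 0.0

    def test_single_model_front_is_indicator(self):
        e = Expression("sub", [Expression.variable(2), Expression.variable(0)])
        front = pareto_filter([FrontModel(e, 3, 0.8)], variable_names=["x1", "x2", "x3"])
        occ = variable_occurrence(front)
        assert occ == {"x1": 1.0, "x2": 0.0, "x3": 1.0}


class TestEvolve:
    def data(self, seed=0, n=40, p=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i+1}" for i in range(p)])

    def test_same_seed_same_front(self):
        X = self.data()
        y = (X.x1 * X.x2 + 0.5 * X.x3).to_numpy()
        cfg = RegressorConfig(population=100, generations=15, seed=21)
        f1 = evolve(X, y, cfg)
        f2 = evolve(X, y, cfg)
        assert f1.to_frame().equals(f2.to_frame())

    def test_constant_target_collapses_to_constant(self):
        X = self.data()
        front = evolve(X, np.full(40, 3.5), RegressorConfig(population=50, generations=5, seed=0))
        assert len(front) == 1
        assert front.models[0].complexity == 1
        assert front.models[0].mae == 0.0

    def test_identity_target_found_at_minimal_complexity(self):
        X = self.data()
        front = evolve(X, X.x4.to_numpy(), RegressorConfig(population=100, generations=10, seed=3))
        best = front.best()
        assert best.r_squared >= 1.0 - 1e-9
        low = min(m.complexity for m in front.models if m.r_squared >= 1 - 1e-9)
        assert low <= 3

    def test_planted_linear_combination_recovered(self):
        X = self.data(seed=5)
        y = (2.0 * X.x1 - X.x3).to_numpy()
        front = evolve(X, y, RegressorConfig(seed=11))
        assert max(m.r_squared for m in front.models) >= 0.99

    def test_front_is_non_dominated_and_sorted(self):
        X = self.data(seed=6)
        y = (X.x1 + X.x2**2).to_numpy()
        front = evolve(X, y, RegressorConfig(population=150, generations=20, seed=2))
        comps = [m.complexity for m in front.models]
        accs = [m.accuracy for m in front.models]
        assert comps == sorted(comps)
        assert accs == sorted(accs)  # strictly better accuracy at higher complexity

    def test_target_in_data_by_name(self):
        X = self.data(seed=7, p=3)
        X["y"] = 3 * X.x1
        front = evolve(X, "y", RegressorConfig(population=60, generations=5, seed=1))
        assert "y" not in front.variable_names
        assert front.best().r_squared >= 1 - 1e-9

    def test_no_finite_data_errors_cleanly(self):
        X = self.data(seed=8, p=1)
        with pytest.raises(ValueError):
            evolve(X.iloc[:, :0], np.zeros(40), RegressorConfig(seed=0))


class TestCanonicalConfigs:
    def test_six_distinct_configurations(self):
        cfgs = canonical_configs(seed=4)
        assert len(cfgs) == 6
        combos = {(c.building_blocks, c.metric) for c in cfgs}
        assert combos == set(itertools.product(BLOCK_SETS, ("r_square", "absolute_error", "hybrid")))
        assert len({c.seed for c in cfgs}) == 6

    def test_overrides_apply(self):
        cfgs = canonical_configs(seed=0, population=77)
        assert all(c.population == 77 for c in cfgs)
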