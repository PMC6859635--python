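"""Real-coded GA: analytic optima, invariants, and a grid-search oracle."""
import numpy as np
import pytest

from pearmedia.factors import FACTOR_BOUNDS, FACTOR_NAMES
from pearmedia.ga import (
    DEFAULT_BOUNDS,
    GAConfig,
    model_objective,
    optimize,
    optimize_all,
)


def test_one_dimensional_quadratic():
    """max of -(A-1)^2 over [0.5, 2]: optimum at A=1, value 0."""
    def obj(X):
        X = np.atleast_2d(X)
        return -(X[:, 0] - 1.0) ** 2

    cfg = GAConfig(bounds=((0.5, 2.0),), generations=80, restarts=3, seed=1)
    res = optimize(obj, cfg)
    assert abs(res.best_x[0] - 1.0) <= 0.02
    assert abs(res.best_value) <= 1e-3


def test_six_dimensional_concave_quadratic_argmax():
    """Argmax at the box center recovered within 1% of range, 9/10 seeds."""
    lo = np.array([b[0] for b in DEFAULT_BOUNDS])
    hi = np.array([b[1] for b in DEFAULT_BOUNDS])
    center, span = (lo + hi) / 2, hi - lo

    def obj(X):
        Z = (np.atleast_2d(X) - center) / span
        return -(Z ** 2).sum(axis=1)

    hits = 0
    for seed in range(1, 11):
        cfg = GAConfig(generations=150, restarts=1, seed=seed)
        res = optimize(obj, cfg)
        if np.all(np.abs(np.array(res.best_x) - center) <= 0.01 * span):
            hits += 1
    assert hits >= 9


def test_every_candidate_stays_inside_bounds():
    lo = np.array([b[0] for b in DEFAULT_BOUNDS])
    hi = np.array([b[1] for b in DEFAULT_BOUNDS])
    seen = {"violations": 0}

    def obj(X):
        X = np.atleast_2d(X)
        if ((X < lo - 1e-12) | (X > hi + 1e-12)).any():
            seen["violations"] += 1
        return X.sum(axis=1)

    optimize(obj, GAConfig(generations=40, restarts=2, seed=3))
    assert seen["violations"] == 0


def test_trace_is_monotone_in_the_optimization_sense():
    def obj(X):
        X = np.atleast_2d(X)
        return np.sin(X).sum(axis=1)

    res = optimize(obj, GAConfig(generations=60, restarts=2, seed=4))
    for trace in res.trace:
        assert (np.diff(trace) >= -1e-12).all()
    res_min = optimize(obj, GAConfig(generations=60, restarts=2, seed=4,
                                     sense="minimize"))
    for trace in res_min.trace:
        assert (np.diff(trace) <= 1e-12).all()


def test_maximize_minimize_duality():
    """max f == -min(-f) under identical seeds (checked on 5 seeds)."""
    def f(X):
        X = np.atleast_2d(X)
        return np.cos(X[:, 0]) * X[:, 1] - X[:, 2]

    for seed in range(5):
        a = optimize(f, GAConfig(generations=30, restarts=1, seed=seed))
        b = optimize(lambda X: -f(X),
                     GAConfig(generations=30, restarts=1, seed=seed,
                              sense="minimize"))
        assert a.best_value == pytest.approx(-b.best_value, rel=1e-12)


def test_best_value_is_reevaluated_objective():
    def obj(X):
        X = np.atleast_2d(X)
        return -(X[:, 0] - 1.3) ** 2

    res = optimize(obj, GAConfig(bounds=((0.5, 2.0),), generations=40,
                                 restarts=2, seed=0))
    assert res.best_value == float(obj(np.atleast_2d(res.best_x))[0])


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(crossover_rate=1.5)
    with pytest.raises(ValueError):
        GAConfig(bounds=((2.0, 1.0),))
    with pytest.raises(ValueError):
        GAConfig(bounds=())
    with pytest.raises(ValueError):
        GAConfig(sense="extremize")


def test_nonfinite_objective_raises():
    def obj(X):
        X = np.atleast_2d(X)
        return np.full(len(X), np.nan)

    with pytest.raises(ValueError, match="non-finite"):
        optimize(obj, GAConfig(generations=5, restarts=1, seed=0))


def test_scalar_objective_accepted():
    res = optimize(lambda x: -(x[0] - 1.0) ** 2,
                   GAConfig(bounds=((0.5, 2.0),), population_size=30,
                            generations=30, restarts=1, seed=0))
    assert abs(res.best_x[0] - 1.0) < 0.05


def test_ga_not_worse_than_grid_search_oracle():
    """Best-of-restarts beats an 11-points-per-axis exhaustive grid."""
    obj = model_objective("Pyrodwarf", "PR")
    axes = [np.linspace(lo, hi, 11) for lo, hi in DEFAULT_BOUNDS]
    grid_best = -np.inf
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    for i in range(0, len(pts), 250_000):
        vals = obj(pts[i:i + 250_000])
        grid_best = max(grid_best, float(vals.max()))
    res = optimize(obj, GAConfig(generations=200, restarts=10, seed=1))
    assert res.best_value >= grid_best - 0.01 * abs(grid_best)


def test_optimize_all_senses_and_notes():
    cfg = GAConfig(generations=30, restarts=1, seed=0)
    table = optimize_all("OHF", cfg, responses=("PR", "STN", "QI"))
    assert list(table["response"]) == ["PR", "STN", "QI"]
    assert list(table["sense"]) == ["maximize", "minimize", "maximize"]
    assert table.loc[table["response"] == "QI", "note"].iloc[0] != ""
    assert set(FACTOR_NAMES) <= set(table.columns)
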