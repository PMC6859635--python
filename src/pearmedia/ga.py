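"""Real-coded genetic algorithm for bound-constrained media optimization.

Candidate solutions are factor vectors (one real gene per media factor).
Selection is roulette-wheel on rank-based weights (rank weighting avoids
the negative-fitness pathologies of raw fitness-proportional selection and
handles minimization symmetrically); crossover is uniform (each gene from
either parent with probability 1/2); mutation adds per-gene Gaussian noise
scaled to a fraction of the factor's range, clipped to the bounds.  The
best solutions pass unchanged (elitism) and the best over independent
restarts is returned, with its objective re-evaluated at return.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .factors import FACTOR_BOUNDS, FACTOR_NAMES, FACTOR_SYMBOLS, FactorVector
from .published import AMBIGUOUS_PROVENANCE, predict

#: optimization sense per growth response
RESPONSE_SENSE: dict[str, str] = {
    "PR": "maximize", "SL": "maximize", "QI": "maximize",
    "STN": "minimize", "Vitri": "minimize",
}

DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = tuple(
    FACTOR_BOUNDS[n] for n in FACTOR_NAMES
)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_scale: float = 0.1  # fraction of each factor's range
    elitism: int = 2
    sense: str = "maximize"
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_rate <= 1.0 or not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError("sense must be 'maximize' or 'minimize'")
        if len(self.bounds) == 0:
            raise ValueError("bounds must be non-empty")
        if any(lo >= hi for lo, hi in self.bounds):
            raise ValueError("each bound must satisfy lo < hi")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")


@dataclass(frozen=True)
class OptimizationResult:
    best_x: FactorVector | tuple
    best_value: float
    sense: str
    trace: tuple[tuple[float, ...], ...]  # per restart: best value by generation
    metadata: dict = field(default_factory=dict)


def _batched(objective: Callable, bounds) -> Callable:
    """Wrap a scalar objective so it accepts an (n, dim) array."""
    probe = np.array([[lo for lo, _ in bounds], [hi for _, hi in bounds]])
    try:
        out = objective(probe)
        if np.shape(out) == (2,):
            return objective
    except Exception:
        pass
    return lambda X: np.array([float(objective(x)) for x in np.atleast_2d(X)])


def model_objective(rootstock: str, response: str) -> Callable:
    """Batched objective evaluating a published model on an (n, 6) array."""

    def f(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        env = {s: X[:, i] for i, s in enumerate(FACTOR_SYMBOLS)}
        return np.atleast_1d(np.asarray(predict(rootstock, response, env), float))

    return f


def _run_one(obj: Callable, config: GAConfig, seed: int) -> tuple[np.ndarray, float, list[float]]:
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    n, d = config.population_size, len(config.bounds)
    sign = 1.0 if config.sense == "maximize" else -1.0

    pop = lo + rng.random((n, d)) * span
    vals = sign * np.asarray(obj(pop), float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("objective returned a non-finite value inside the bounds")
    trace: list[float] = []
    for _ in range(config.generations):
        order = np.argsort(-vals, kind="stable")  # best first
        trace.append(float(sign * vals[order[0]]))
        ranks = np.empty(n)
        ranks[order] = np.arange(n, 0, -1)  # best gets weight n
        probs = ranks / ranks.sum()
        elite_idx = order[:config.elitism]
        elites = pop[elite_idx].copy()
        elite_vals = vals[elite_idx].copy()

        parents_i = rng.choice(n, size=n - config.elitism, p=probs)
        mates_i = rng.choice(n, size=n - config.elitism, p=probs)
        children = pop[parents_i].copy()
        do_cross = rng.random(n - config.elitism) < config.crossover_rate
        take_mate = rng.random((n - config.elitism, d)) < 0.5
        mask = do_cross[:, None] & take_mate
        children[mask] = pop[mates_i][mask]
        mut = rng.random((n - config.elitism, d)) < config.mutation_rate
        noise = rng.normal(0.0, 1.0, size=children.shape) * (config.mutation_scale * span)
        children = np.clip(children + mut * noise, lo, hi)

        child_vals = sign * np.asarray(obj(children), float)
        if not np.all(np.isfinite(child_vals)):
            raise ValueError("objective returned a non-finite value inside the bounds")
        pop = np.vstack([elites, children])
        vals = np.concatenate([elite_vals, child_vals])
    i = int(np.argmax(vals))
    trace.append(float(sign * vals[i]))
    return pop[i], float(sign * vals[i]), trace


def optimize(objective: Callable, config: GAConfig) -> OptimizationResult:
    """Best-of-restarts GA optimization of ``objective`` over the bounds box.

    ``objective`` may be batched (accepting an (n, d) array) or scalar.
    Restart r uses seed ``config.seed + r``; the returned best value is the
    objective re-evaluated at the returned point.
    """
    obj = _batched(objective, config.bounds)
    best_x, best_v, traces = None, None, []
    better = (lambda a, b: a > b) if config.sense == "maximize" else (lambda a, b: a < b)
    for r in range(config.restarts):
        x, v, trace = _run_one(obj, config, config.seed + r)
        traces.append(tuple(trace))
        if best_v is None or better(v, best_v):
            best_x, best_v = x, v
    best_value = float(np.asarray(obj(np.atleast_2d(best_x)), float)[0])
    best_x = tuple(float(v) for v in best_x)
    x_out = FactorVector(*best_x) if len(best_x) == len(FACTOR_NAMES) else best_x
    return OptimizationResult(
        best_x=x_out, best_value=best_value, sense=config.sense,
        trace=tuple(traces),
    )


def optimize_all(rootstock: str, config: GAConfig | None = None,
                 responses: Sequence[str] | None = None) -> pd.DataFrame:
    """GA-optimize every published model of one rootstock.

    Returns a table with one row per response: the optimization sense, the
    optimum value and the six optimal factor levels.  QI rows carry a note:
    the source attributes its printed QI optima to the RBF-network models
    while captioning the table as GEP output; this pipeline optimizes the
    published equations and flags the ambiguity instead of guessing.
    """
    config = config or GAConfig()
    responses = responses or list(RESPONSE_SENSE)
    rows = []
    for resp in responses:
        sense = RESPONSE_SENSE[resp]
        cfg = replace(config, sense=sense)
        res = optimize(model_objective(rootstock, resp), cfg)
        row = {
            "response": resp,
            "sense": sense,
            "optimum": res.best_value,
            **dict(zip(FACTOR_NAMES, res.best_x)),
            "note": ("printed optimum attributed to RBFNN in source prose"
                     if resp in AMBIGUOUS_PROVENANCE else ""),
        }
        rows.append(row)
    return pd.DataFrame(rows)
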