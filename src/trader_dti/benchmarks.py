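"""Standard continuous test functions and the multi-run benchmark protocol.

The registry holds the classic unimodal / multimodal / fixed-dimension test
functions used throughout the metaheuristics literature (sphere, Rosenbrock,
Rastrigin, Ackley, Griewank, Schwefel 2.26, the two penalized functions, and
three two-dimensional classics).  ``run_trials`` repeats independent seeded
optimizer executions and summarizes them as mean +/- std plus the overall
best, with the per-run convergence matrix; ``rank_sum_compare`` is the
two-sided Wilcoxon rank-sum comparison used to contrast result samples of
two stochastic optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import stats

from .trader import ObjectiveFunction, TraderConfig, run

__all__ = [
    "BenchmarkFunction",
    "TrialSummary",
    "RankSumResult",
    "REGISTRY",
    "get_benchmark",
    "run_trials",
    "rank_sum_compare",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dimension: int
    bounds: tuple[float, float]
    evaluate: Callable[[np.ndarray], float]
    known_optimum: float | None = None
    argmin: np.ndarray | None = None

    def as_objective(self) -> ObjectiveFunction:
        return ObjectiveFunction(self.evaluate, self.dimension, self.bounds)


def _sphere(x):
    return float(np.sum(x * x))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x):
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2 * np.pi * x)))


def _ackley(x):
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


_SCHWEFEL_ARGMIN = 420.968746


def _schwefel(x):
    # shifted so the optimum value is ~0 at x_i = 420.9687
    return float(418.9829 * x.size - np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _penalty_u(x, a, k, m):
    out = np.zeros_like(x)
    over = x > a
    under = x < -a
    out[over] = k * (x[over] - a) ** m
    out[under] = k * (-x[under] - a) ** m
    return out


def _penalized1(x):
    n = x.size
    y = 1.0 + (x + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / n * term + np.sum(_penalty_u(x, 10.0, 100.0, 4)))


def _penalized2(x):
    term = (
        np.sin(3 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2 * np.pi * x[-1]) ** 2)
    )
    return float(0.1 * term + np.sum(_penalty_u(x, 5.0, 100.0, 4)))


def _branin(x):
    a, b, c = 1.0, 5.1 / (4 * np.pi**2), 5.0 / np.pi
    r, s, t = 6.0, 10.0, 1.0 / (8 * np.pi)
    return float(a * (x[1] - b * x[0] ** 2 + c * x[0] - r) ** 2 + s * (1 - t) * np.cos(x[0]) + s)


def _goldstein_price(x):
    x1, x2 = x[0], x[1]
    t1 = 1 + (x1 + x2 + 1) ** 2 * (19 - 14 * x1 + 3 * x1**2 - 14 * x2 + 6 * x1 * x2 + 3 * x2**2)
    t2 = 30 + (2 * x1 - 3 * x2) ** 2 * (
        18 - 32 * x1 + 12 * x1**2 + 48 * x2 - 36 * x1 * x2 + 27 * x2**2
    )
    return float(t1 * t2)


def _six_hump_camel(x):
    x1, x2 = x[0], x[1]
    return float(
        (4 - 2.1 * x1**2 + x1**4 / 3) * x1**2 + x1 * x2 + (-4 + 4 * x2**2) * x2**2
    )


# name -> (factory(dim) kwargs); scalable entries accept any dimension
_SCALABLE = {
    "sphere": (_sphere, (-100.0, 100.0), 0.0, lambda n: np.zeros(n)),
    "rosenbrock": (_rosenbrock, (-30.0, 30.0), 0.0, lambda n: np.ones(n)),
    "rastrigin": (_rastrigin, (-5.12, 5.12), 0.0, lambda n: np.zeros(n)),
    "ackley": (_ackley, (-32.0, 32.0), 0.0, lambda n: np.zeros(n)),
    "griewank": (_griewank, (-600.0, 600.0), 0.0, lambda n: np.zeros(n)),
    "schwefel226": (_schwefel, (-500.0, 500.0), 0.0, lambda n: np.full(n, _SCHWEFEL_ARGMIN)),
    "penalized1": (_penalized1, (-50.0, 50.0), 0.0, lambda n: np.full(n, -1.0)),
    "penalized2": (_penalized2, (-50.0, 50.0), 0.0, lambda n: np.ones(n)),
}

_FIXED = {
    "branin": (_branin, (-5.0, 15.0), 0.397887, np.array([np.pi, 2.275])),
    "goldstein_price": (_goldstein_price, (-2.0, 2.0), 3.0, np.array([0.0, -1.0])),
    "six_hump_camel": (_six_hump_camel, (-5.0, 5.0), -1.0316285, np.array([0.0898, -0.7126])),
}

REGISTRY: tuple[str, ...] = tuple(_SCALABLE) + tuple(_FIXED)


def get_benchmark(name: str, dimension: int | None = None) -> BenchmarkFunction:
    """Look up a registered test function; scalable functions default to 10-D,
    fixed-dimension classics are always 2-D."""
    if name in _SCALABLE:
        fn, bounds, opt, argmin = _SCALABLE[name]
        dim = 10 if dimension is None else int(dimension)
        if dim < 1 or (name == "rosenbrock" and dim < 2):
            raise ValueError(f"invalid dimension {dim} for {name}")
        return BenchmarkFunction(name, dim, bounds, fn, opt, argmin(dim))
    if name in _FIXED:
        fn, bounds, opt, argmin = _FIXED[name]
        if dimension not in (None, 2):
            raise ValueError(f"{name} is a fixed 2-dimensional function")
        return BenchmarkFunction(name, 2, bounds, fn, opt, argmin)
    raise KeyError(f"unknown benchmark {name!r}; registered: {', '.join(REGISTRY)}")


@dataclass
class TrialSummary:
    """Multi-run summary: per-run best values, their mean/std (population
    form), the overall best, and the executions x iterations convergence
    matrix (row e is the best-so-far history of execution e)."""

    function: str
    best_values: np.ndarray
    convergence: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.best_values))

    @property
    def std(self) -> float:
        return float(np.std(self.best_values))

    @property
    def overall_best(self) -> float:
        return float(np.min(self.best_values))


def run_trials(
    fn: BenchmarkFunction, config: TraderConfig, executions: int
) -> TrialSummary:
    """Repeat ``executions`` independent optimizer runs on ``fn``.

    Execution ``e`` uses seed ``config.seed + e`` so runs are independent yet
    reproducible.  The function's own bounds and dimension override whatever
    the config carries.
    """
    if executions < 1:
        raise ValueError("executions must be >= 1")
    objective = fn.as_objective()
    bests = np.empty(executions)
    histories = np.empty((executions, config.max_iterations))
    for e in range(executions):
        cfg = replace(config, seed=config.seed + e, bounds=fn.bounds)
        try:
            best, history = run(cfg, objective)
        except Exception as err:  # annotate with the execution index
            raise RuntimeError(f"execution {e} failed: {err}") from err
        bests[e] = best.objective_value
        histories[e] = history
    return TrialSummary(fn.name, bests, histories)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.p_value


def rank_sum_compare(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Small tie-free samples use the exact null distribution (identical to
    exhaustive permutation enumeration); larger or tied samples use the
    tie-corrected normal approximation.  Two samples whose values are all
    identical are degenerate: p = 1 with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankSumResult(float(a.size * b.size / 2.0), 1.0, True)
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), False)
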