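"""The Trader population-based metaheuristic.

Trader maintains a population of ``C`` candidate solutions partitioned among
``T`` traders (groups).  Each iteration proceeds through five phases:

1. *Group allocation* — every trader receives ``NB_i = 2 + round(P_i / sum(P)
   * (C - 2T))`` solutions, proportional to its property ``P_i``; membership
   is decided by a ranked competition (best solutions are claimed first by
   the wealthiest traders, round-robin).
2. *Master→slave distribution* — the best member of each group (the master)
   broadcasts randomly chosen variable values to every other member (slave).
3. *Slave self-change* — each slave perturbs a few of its own variables
   multiplicatively, ``v <- v + k * u * v`` with ``k`` a random sign and
   ``u ~ U[0, 1)``.
4. *Master exchange* — each group's master imports randomly chosen variable
   values from the master of another, randomly selected, group.
5. *Property update* — each trader's property is recomputed from the
   objective values of its members.

Every candidate modification passes through strict greedy acceptance: a
trial replaces the incumbent only when it strictly lowers the objective, so
the best objective value seen never regresses.  All randomness flows through
one seeded :class:`numpy.random.Generator` owned by the run, drawn in a
fixed, documented order, which makes runs bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSolution",
    "ObjectiveFunction",
    "TraderConfig",
    "TraderState",
    "init_population",
    "allocate_groups",
    "greedy_accept",
    "master_slave_distribute",
    "slave_self_change",
    "master_exchange",
    "update_properties",
    "run",
]

#: floor used for non-positive member contributions under literal_sum
_PROPERTY_EPS = 1e-12


@dataclass
class CandidateSolution:
    """One member of the population: a real vector, its group, and its cached
    objective value (lower is better)."""

    variables: np.ndarray
    group: int | None = None
    objective_value: float = float("nan")

    def copy(self) -> "CandidateSolution":
        return CandidateSolution(self.variables.copy(), self.group, self.objective_value)


@dataclass(frozen=True)
class ObjectiveFunction:
    """A deterministic vector -> scalar objective with its search box."""

    evaluate: Callable[[np.ndarray], float]
    dimension: int
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def __call__(self, x: np.ndarray) -> float:
        return float(self.evaluate(x))


@dataclass(frozen=True)
class TraderConfig:
    """Run configuration.

    ``bounds`` is either a scalar ``(lo, hi)`` pair applied to every variable
    or a pair of per-variable arrays.  ``property_mode`` selects how trader
    property is recomputed from member objective values:

    - ``"inverse_fitness"`` (default): each member contributes ``1/(1 + OF)``
      so better (smaller-objective) groups grow richer and are allocated more
      solutions;
    - ``"literal_sum"``: each member contributes its raw objective value, so
      under minimization worse groups are allocated more solutions.
    """

    population_size: int
    num_traders: int
    max_iterations: int
    bounds: tuple = (-1.0, 1.0)
    seed: int = 0
    property_mode: str = "inverse_fitness"
    minimize: bool = True

    def validate(self) -> None:
        if self.num_traders < 1:
            raise ValueError("num_traders must be >= 1")
        if self.population_size < 2 * self.num_traders:
            raise ValueError(
                f"population_size ({self.population_size}) must be at least "
                f"2 * num_traders ({2 * self.num_traders}) so every group keeps >= 2 members"
            )
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.property_mode not in ("inverse_fitness", "literal_sum"):
            raise ValueError(f"unknown property_mode: {self.property_mode!r}")
        if not self.minimize:
            raise ValueError("only minimization is supported")

    def bound_arrays(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.bounds
        lo = np.broadcast_to(np.asarray(lo, dtype=float), (n,)).copy()
        hi = np.broadcast_to(np.asarray(hi, dtype=float), (n,)).copy()
        if np.any(lo >= hi):
            raise ValueError("each lower bound must be < its upper bound")
        return lo, hi

    def to_dict(self) -> dict:
        b = self.bounds
        bounds = [np.asarray(b[0]).tolist(), np.asarray(b[1]).tolist()]
        return {
            "population_size": self.population_size,
            "num_traders": self.num_traders,
            "max_iterations": self.max_iterations,
            "bounds": bounds,
            "seed": self.seed,
            "property_mode": self.property_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraderConfig":
        d = dict(d)
        if "bounds" in d:
            lo, hi = d["bounds"]
            d["bounds"] = (lo, hi) if np.isscalar(lo) else (np.asarray(lo), np.asarray(hi))
        return cls(**d)


@dataclass
class TraderState:
    """Mutable optimizer state.

    The population is held columnar for speed: ``X`` is the ``(C, n)`` matrix
    of variable vectors, ``f`` the cached objective values, ``groups`` the
    per-solution trader index (``-1`` while unassigned).  ``members`` lists,
    per trader, member row indices in claiming order.
    """

    X: np.ndarray
    f: np.ndarray
    groups: np.ndarray
    properties: np.ndarray
    group_sizes: np.ndarray
    members: list = field(default_factory=list)
    iteration: int = 0
    best_x: np.ndarray | None = None
    best_f: float = np.inf
    best_history: list = field(default_factory=list)
    accept_counts: dict = field(default_factory=dict)

    @property
    def best(self) -> CandidateSolution:
        return CandidateSolution(np.array(self.best_x), None, self.best_f)

    def _note(self, op: str, accepted: bool) -> None:
        a, r = self.accept_counts.get(op, (0, 0))
        self.accept_counts[op] = (a + accepted, r + (not accepted))


def init_population(
    config: TraderConfig,
    objective: ObjectiveFunction,
    rng: np.random.Generator | None = None,
) -> TraderState:
    """Draw ``C`` solutions uniformly inside the bounds and evaluate them.

    All traders start with the same property (1); the scale cancels in the
    allocation rule.  A non-finite objective value on an initial point aborts
    with a diagnostic naming the point.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = objective.dimension
    lo, hi = config.bound_arrays(n)
    C, T = config.population_size, config.num_traders
    X = rng.uniform(lo, hi, size=(C, n))
    f = np.empty(C)
    for i in range(C):
        fi = objective(X[i])
        if not np.isfinite(fi):
            raise ValueError(
                f"objective returned non-finite value {fi!r} on initial point "
                f"#{i}: {X[i].tolist()}"
            )
        f[i] = fi
    state = TraderState(
        X=X,
        f=f,
        groups=np.full(C, -1, dtype=int),
        properties=np.ones(T),
        group_sizes=np.zeros(T, dtype=int),
    )
    ibest = int(np.argmin(f))
    state.best_x = X[ibest].copy()
    state.best_f = float(f[ibest])
    return state


def allocate_groups(state: TraderState, config: TraderConfig) -> TraderState:
    """Allocate solutions to traders proportionally to property.

    ``NB_i = 2 + round(P_i / sum(P) * (C - 2T))``; the rounding residual is
    corrected on the groups with the largest (deficit) or smallest (excess)
    fractional share until the sizes conserve ``C``, never letting a group
    drop below 2.  Membership is a ranked competition: solutions sorted by
    objective ascending are claimed in rounds, traders picking in property-
    descending order until each reaches its quota.
    """
    P = np.asarray(state.properties, dtype=float)
    if np.any(P <= 0) or not np.all(np.isfinite(P)):
        raise ValueError("properties must be strictly positive and finite")
    C = state.X.shape[0]
    T = P.size
    share = P / P.sum() * (C - 2 * T)
    nb = 2 + np.round(share).astype(int)
    frac = share - np.round(share)
    residual = C - int(nb.sum())
    while residual != 0:
        if residual > 0:
            i = int(np.argmax(frac))
            nb[i] += 1
            frac[i] -= 1.0
            residual -= 1
        else:
            candidates = np.where(nb > 2)[0]
            i = int(candidates[np.argmin(frac[candidates])])
            nb[i] -= 1
            frac[i] += 1.0
            residual += 1
    if nb.min() < 2 or nb.sum() != C:  # pragma: no cover - internal guard
        raise AssertionError("group allocation violated size invariants")

    order = np.argsort(state.f, kind="stable")
    trader_order = np.argsort(-P, kind="stable")
    quota = nb.copy()
    members: list[list[int]] = [[] for _ in range(T)]
    groups = np.full(C, -1, dtype=int)
    pos = 0
    while pos < C:
        for t in trader_order:
            if quota[t] > 0:
                sol = int(order[pos])
                groups[sol] = t
                members[t].append(sol)
                quota[t] -= 1
                pos += 1
                if pos == C:
                    break
    state.group_sizes = nb
    state.groups = groups
    state.members = [np.asarray(m, dtype=int) for m in members]
    return state


def greedy_accept(
    trial: np.ndarray,
    incumbent: CandidateSolution,
    objective: ObjectiveFunction,
) -> CandidateSolution:
    """Return the trial as a new solution iff it strictly improves the
    incumbent's objective; ties and non-finite trial objectives are rejected."""
    ft = objective(np.asarray(trial, dtype=float))
    if np.isfinite(ft) and ft < incumbent.objective_value:
        return CandidateSolution(np.array(trial, dtype=float), incumbent.group, ft)
    if not np.isfinite(ft):
        logger.debug("rejected trial with non-finite objective %r", ft)
    return incumbent


def _try_accept(
    state: TraderState, j: int, trial: np.ndarray, objective: ObjectiveFunction, op: str
) -> bool:
    """In-place greedy acceptance for population member ``j``."""
    ft = objective(trial)
    ok = np.isfinite(ft) and ft < state.f[j]
    if ok:
        state.X[j] = trial
        state.f[j] = ft
    state._note(op, bool(ok))
    return bool(ok)


def _group_master(state: TraderState, group: int) -> int:
    m = state.members[group]
    return int(m[np.argmin(state.f[m])])


def master_slave_distribute(
    state: TraderState,
    group: int,
    objective: ObjectiveFunction,
    rng: np.random.Generator,
) -> TraderState:
    """Broadcast master values to each slave by R positional copies.

    For each slave, draw ``R ~ U{1..n}``, then ``R`` indices ``p ~ U{1..n}``
    (with replacement) and set ``trial[p] = master[p]``; the trial passes
    through greedy acceptance.  The master itself is unchanged.
    """
    n = state.X.shape[1]
    master = _group_master(state, group)
    for j in state.members[group]:
        if j == master:
            continue
        R = int(rng.integers(1, n + 1))
        idx = rng.integers(0, n, size=R)
        trial = state.X[j].copy()
        trial[idx] = state.X[master][idx]
        _try_accept(state, int(j), trial, objective, "master_slave")
    return state


def slave_self_change(
    state: TraderState,
    group: int,
    objective: ObjectiveFunction,
    config: TraderConfig,
    rng: np.random.Generator,
) -> TraderState:
    """Multiplicative self-perturbation of each slave.

    Draw ``R ~ U{1..max(1, n // 10)}``; for each of the R steps draw a fresh
    index ``M``, a sign ``k`` in {-1, +1} and ``u ~ U[0, 1)``, and set
    ``trial[M] <- trial[M] + k * u * trial[M]``.  The trial is clamped to the
    bounds and submitted through greedy acceptance.
    """
    n = state.X.shape[1]
    lo, hi = config.bound_arrays(n)
    rmax = max(1, n // 10)
    master = _group_master(state, group)
    for j in state.members[group]:
        if j == master:
            continue
        R = int(rng.integers(1, rmax + 1))
        trial = state.X[j].copy()
        for _ in range(R):
            M = int(rng.integers(0, n))
            k = 1.0 if rng.integers(0, 2) else -1.0
            u = rng.random()
            trial[M] = trial[M] + k * u * trial[M]
        np.clip(trial, lo, hi, out=trial)
        _try_accept(state, int(j), trial, objective, "slave_self")
    return state


def master_exchange(
    state: TraderState,
    objective: ObjectiveFunction,
    rng: np.random.Generator,
) -> TraderState:
    """Exchange variable values among the group masters.

    For each group ``j`` (in index order) an exporter group ``k != j`` is
    chosen uniformly; ``R ~ U{1..n}`` positional copies from master_k build a
    trial for master_j, accepted greedily.  With a single trader the operator
    is a no-op.
    """
    T = len(state.members)
    if T < 2:
        logger.debug("master_exchange skipped: single trader")
        return state
    n = state.X.shape[1]
    for g in range(T):
        other = int(rng.integers(0, T - 1))
        if other >= g:
            other += 1
        mj = _group_master(state, g)
        mk = _group_master(state, other)
        R = int(rng.integers(1, n + 1))
        idx = rng.integers(0, n, size=R)
        trial = state.X[mj].copy()
        trial[idx] = state.X[mk][idx]
        _try_accept(state, mj, trial, objective, "master_exchange")
    return state


def update_properties(state: TraderState, config: TraderConfig) -> TraderState:
    """Recompute trader properties from member objective values.

    ``inverse_fitness``: each member contributes ``1 / (1 + OF)``; when the
    population contains negative objectives the contributions use
    ``OF - min(0, min OF)`` so the transform stays positive (identical to
    ``1/(1+OF)`` for non-negative objectives).  ``literal_sum``: each member
    contributes its raw objective, floored at a small epsilon when it would
    otherwise drive a property non-positive.
    """
    T = len(state.members)
    P = np.empty(T)
    if config.property_mode == "inverse_fitness":
        shift = min(0.0, float(state.f.min()))
        for g in range(T):
            P[g] = np.sum(1.0 / (1.0 + state.f[state.members[g]] - shift))
    else:
        for g in range(T):
            contrib = state.f[state.members[g]].copy()
            if np.any(contrib <= 0):
                contrib = np.maximum(contrib, _PROPERTY_EPS)
                if not getattr(state, "_warned_literal_floor", False):
                    logger.warning(
                        "literal_sum property: non-positive objective contributions "
                        "floored at %g", _PROPERTY_EPS,
                    )
                    state._warned_literal_floor = True
            P[g] = contrib.sum()
    state.properties = P
    return state


def run(
    config: TraderConfig,
    objective: ObjectiveFunction,
) -> tuple[CandidateSolution, np.ndarray]:
    """Run the full Trader loop and return the best solution ever seen plus
    the per-iteration best-objective history (non-increasing by construction).

    Per-iteration schedule: allocate groups -> master/slave distribution for
    every group -> slave self-change for every group -> master exchange ->
    property update.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = init_population(config, objective, rng)
    T = config.num_traders
    for it in range(config.max_iterations):
        allocate_groups(state, config)
        for g in range(T):
            master_slave_distribute(state, g, objective, rng)
        for g in range(T):
            slave_self_change(state, g, objective, config, rng)
        master_exchange(state, objective, rng)
        update_properties(state, config)
        state.iteration = it + 1
        i = int(np.argmin(state.f))
        if state.f[i] < state.best_f:
            state.best_f = float(state.f[i])
            state.best_x = state.X[i].copy()
        state.best_history.append(state.best_f)
        logger.info("iteration %d best objective %.6g", it + 1, state.best_f)
    logger.debug("operator accept/reject counts: %s", state.accept_counts)
    return state.best, np.asarray(state.best_history)


def save_run(path, best: CandidateSolution, history: np.ndarray, config: TraderConfig) -> None:
    """Serialize a run result (best vector + objective + config echo) as JSON."""
    payload = {
        "best_variables": np.asarray(best.variables).tolist(),
        "best_objective": best.objective_value,
        "config": config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
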