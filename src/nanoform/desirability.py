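"""Derringer–Suich desirability scoring and multi-response optimization.

Each predicted response is mapped onto a desirability :math:`d \\in [0, 1]`
against a goal.  For a minimize goal with limits :math:`(L, U)` and weight
:math:`w`,

.. math::

   d(y) = \\begin{cases} 1 & y \\le L \\\\
   \\left(\\dfrac{U - y}{U - L}\\right)^{w} & L < y < U \\\\
   0 & y \\ge U, \\end{cases}

with the mirrored form for maximize goals and an indicator for in-range
goals.  The overall desirability is the importance-weighted geometric mean

.. math:: D = \\Big(\\prod_i d_i^{r_i}\\Big)^{1 / \\sum_i r_i},

so a single fully undesirable response (:math:`d_i = 0`) zeroes the whole
score.  Optimization runs multi-start bounded L-BFGS-B from Latin-hypercube
starts over the coded factor cuboid; because the paper-style problems are
smooth low-dimensional polynomials, a modest number of starts (64) already
makes the result seed-insensitive.

In-range goals on *factors* act as hard box constraints: they clip the
optimizer's search bounds, contribute :math:`d = 1` inside, and (by
default, matching common DoE-software behaviour) their importances still
enter the :math:`\\sum r_i` denominator — a monotone rescaling of
:math:`D` that cannot change the ranking of solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .doe import FactorSpec
from .rsm import QuadraticModel

__all__ = [
    "GoalError",
    "Goal",
    "Solution",
    "DesignSpace",
    "individual_desirability",
    "overall_desirability",
    "desirability_at",
    "optimize_desirability",
    "design_space",
]

#: solutions closer than this in coded Euclidean distance are merged
DEDUP_RADIUS = 0.02

GOAL_KINDS = ("minimize", "maximize", "in_range")


class GoalError(ValueError):
    """Invalid desirability goal definition."""


@dataclass(frozen=True)
class Goal:
    """A desirability target for one response or factor.

    Parameters
    ----------
    target_name
        Response name (for minimize/maximize/in_range response goals) or
        factor name (in_range only).
    kind
        ``"minimize"``, ``"maximize"`` or ``"in_range"``.
    lower, upper
        Goal limits; ``lower < upper``.
    weight
        Curvature exponent of the one-sided desirability ramp (> 0).
    importance
        Integer 1–5; the exponent :math:`r_i` in the geometric mean.
    """

    target_name: str
    kind: str
    lower: float
    upper: float
    weight: float = 1.0
    importance: int = 1

    def __post_init__(self) -> None:
        if self.kind not in GOAL_KINDS:
            raise GoalError(f"unknown goal kind {self.kind!r}; expected one of {GOAL_KINDS}")
        if not self.lower < self.upper:
            raise GoalError(
                f"goal {self.target_name!r}: require lower < upper, "
                f"got ({self.lower}, {self.upper})"
            )
        if not self.weight > 0:
            raise GoalError(f"goal {self.target_name!r}: weight must be positive")
        if int(self.importance) != self.importance or not 1 <= self.importance <= 5:
            raise GoalError(
                f"goal {self.target_name!r}: importance must be an integer in 1..5"
            )


def individual_desirability(value, goal: Goal):
    """Desirability of a value under one goal; vectorized over ``value``."""
    v = np.asarray(value, dtype=float)
    span = goal.upper - goal.lower
    if goal.kind == "minimize":
        ramp = np.clip((goal.upper - v) / span, 0.0, 1.0)
        d = ramp**goal.weight
    elif goal.kind == "maximize":
        ramp = np.clip((v - goal.lower) / span, 0.0, 1.0)
        d = ramp**goal.weight
    else:  # in_range
        d = np.where((v >= goal.lower) & (v <= goal.upper), 1.0, 0.0)
    return float(d) if np.isscalar(value) else d


def overall_desirability(individual_d: Sequence[float], importances: Sequence[int]):
    """Importance-weighted geometric mean of individual desirabilities.

    Accepts 1-D lists (one d per goal) or a 2-D array of shape
    (n_goals, n_points) for vectorized evaluation.
    """
    d = np.asarray(individual_d, dtype=float)
    r = np.asarray(importances, dtype=float)
    if d.shape[0] == 0:
        raise GoalError("at least one desirability value is required")
    if d.shape[0] != r.shape[0]:
        raise GoalError("individual_d and importances must have the same length")
    if np.any((d < 0) | (d > 1)):
        raise GoalError("individual desirabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logd = np.log(d)  # -inf where d == 0 -> D == 0, the intended limit
    weighted = np.tensordot(r, logd, axes=(0, 0)) / r.sum()
    out = np.exp(weighted)
    return float(out) if d.ndim == 1 else out


# ---------------------------------------------------------------------------
# optimization over the factor cuboid


def _split_goals(
    models: Sequence[QuadraticModel], goals: Sequence[Goal]
) -> tuple[dict[str, QuadraticModel], list[Goal], list[Goal]]:
    by_response = {m.response_name: m for m in models}
    factor_names = {f.name for f in models[0].factors}
    response_goals, factor_goals = [], []
    for g in goals:
        if g.target_name in by_response:
            response_goals.append(g)
        elif g.target_name in factor_names:
            if g.kind != "in_range":
                raise GoalError(
                    f"factor goal {g.target_name!r} must be in_range, got {g.kind!r}"
                )
            factor_goals.append(g)
        else:
            raise GoalError(
                f"goal {g.target_name!r} names neither a fitted response "
                f"({sorted(by_response)}) nor a design factor ({sorted(factor_names)})"
            )
    return by_response, response_goals, factor_goals


def desirability_at(
    models: Sequence[QuadraticModel],
    goals: Sequence[Goal],
    coded: np.ndarray,
    include_range_importances: bool = True,
) -> np.ndarray:
    """Overall desirability D at coded points (n × k); vectorized.

    Factor in-range goals are assumed satisfied (the optimizer enforces
    them through its bounds); with ``include_range_importances`` their
    importances still count in the geometric-mean denominator.
    """
    by_response, response_goals, factor_goals = _split_goals(models, goals)
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    ds, rs = [], []
    for g in response_goals:
        pred = by_response[g.target_name].predict_coded(coded)
        ds.append(individual_desirability(pred, g))
        rs.append(g.importance)
    if include_range_importances:
        for g in factor_goals:
            ds.append(np.ones(coded.shape[0]))
            rs.append(g.importance)
    return overall_desirability(np.asarray(ds), rs)


@dataclass
class Solution:
    """One optimizer solution: settings, predictions and desirabilities."""

    rank: int
    actual_settings: dict[str, float]
    coded_settings: np.ndarray = field(repr=False)
    predicted: dict[str, float] = field(default_factory=dict)
    individual_d: dict[str, float] = field(default_factory=dict)
    overall_D: float = float("nan")


def _coded_bounds(
    factors: Sequence[FactorSpec], factor_goals: Sequence[Goal]
) -> list[tuple[float, float]]:
    ranges = {g.target_name: (g.lower, g.upper) for g in factor_goals}
    bounds = []
    for f in factors:
        lo, hi = ranges.get(f.name, (f.low, f.high))
        lo, hi = max(lo, f.low), min(hi, f.high)
        bounds.append((f.code(lo), f.code(hi)))
    return bounds


def optimize_desirability(
    models: Sequence[QuadraticModel],
    goals: Sequence[Goal],
    n_starts: int = 64,
    seed: int = 0,
    include_range_importances: bool = True,
    max_solutions: int = 10,
) -> list[Solution]:
    """Locate the factor settings maximizing overall desirability.

    Runs ``n_starts`` bounded L-BFGS-B searches from a seeded
    Latin-hypercube sample of the coded cuboid, merges converged points
    closer than :data:`DEDUP_RADIUS` coded units, and returns solutions
    ranked by D descending (near-ties broken by the first minimize-goal
    prediction, ascending — "smaller particles win").
    """
    if n_starts < 1:
        raise GoalError("n_starts must be >= 1")
    by_response, response_goals, factor_goals = _split_goals(models, goals)
    factors = models[0].factors
    bounds = _coded_bounds(factors, factor_goals)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x: np.ndarray) -> float:
        return -float(
            desirability_at(models, goals, x[None, :], include_range_importances)[0]
        )

    sampler = qmc.LatinHypercube(d=len(factors), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    candidates: list[np.ndarray] = []
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        candidates.append(np.clip(res.x, lo, hi))

    # merge candidates within the dedup radius, keeping the better one
    scored = sorted(
        ((x, -objective(x)) for x in candidates), key=lambda t: t[1], reverse=True
    )
    kept: list[tuple[np.ndarray, float]] = []
    for x, D in scored:
        if all(np.linalg.norm(x - k) >= DEDUP_RADIUS for k, _ in kept):
            kept.append((x, D))

    min_goal = next((g for g in response_goals if g.kind == "minimize"), None)

    def tie_break(item: tuple[np.ndarray, float]) -> tuple[float, float]:
        x, D = item
        secondary = (
            float(by_response[min_goal.target_name].predict_coded(x[None, :])[0])
            if min_goal is not None
            else 0.0
        )
        return (-np.round(D, 6), secondary)

    kept.sort(key=tie_break)
    solutions = []
    for rank, (x, D) in enumerate(kept[:max_solutions], start=1):
        predicted = {
            name: float(m.predict_coded(x[None, :])[0]) for name, m in by_response.items()
        }
        individual = {
            g.target_name: individual_desirability(predicted[g.target_name], g)
            for g in response_goals
        }
        solutions.append(
            Solution(
                rank=rank,
                actual_settings={
                    f.name: float(f.decode(c)) for f, c in zip(factors, x)
                },
                coded_settings=x,
                predicted=predicted,
                individual_d=individual,
                overall_D=D,
            )
        )
    return solutions


def solutions_frame(solutions: Sequence[Solution]) -> pd.DataFrame:
    """Flatten a solution list into one tidy row per solution."""
    rows = []
    for s in solutions:
        row: dict[str, float] = {"rank": s.rank}
        row.update({f"{k}": v for k, v in s.actual_settings.items()})
        row.update({f"pred_{k}": v for k, v in s.predicted.items()})
        row.update({f"d_{k}": v for k, v in s.individual_d.items()})
        row["overall_D"] = s.overall_D
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design space / overlay region


@dataclass
class DesignSpace:
    """Feasibility mask of response constraints over the factor cuboid."""

    factors: list[FactorSpec]
    axes: list[np.ndarray] = field(repr=False)  # actual-unit grid per factor
    mask: np.ndarray = field(repr=False)  # boolean, shape res^k
    constraints: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def feasible_fraction(self) -> float:
        return float(self.mask.mean())

    def to_frame(self) -> pd.DataFrame:
        grids = np.meshgrid(*self.axes, indexing="ij")
        data = {f.name: g.ravel() for f, g in zip(self.factors, grids)}
        data["feasible"] = self.mask.ravel()
        return pd.DataFrame(data)


_COMPARATORS = {
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


def design_space(
    models: Sequence[QuadraticModel],
    constraints: Sequence[tuple[str, str, float]],
    grid_resolution: int = 21,
) -> DesignSpace:
    """Evaluate response constraints on a regular actual-units grid.

    ``constraints`` are ``(response_name, "<=" or ">=", threshold)``
    triples; the mask is true where every constraint holds simultaneously
    (the grey overlay region of DoE software).
    """
    if grid_resolution < 2:
        raise GoalError("grid_resolution must be >= 2")
    by_response = {m.response_name: m for m in models}
    for name, comp, _ in constraints:
        if name not in by_response:
            raise GoalError(f"constraint names unknown response {name!r}")
        if comp not in _COMPARATORS:
            raise GoalError(f"comparator must be one of {sorted(_COMPARATORS)}, got {comp!r}")
    factors = models[0].factors
    axes = [np.linspace(f.low, f.high, grid_resolution) for f in factors]
    coded_axes = [np.array([f.code(a) for a in ax]) for f, ax in zip(factors, axes)]
    grids = np.meshgrid(*coded_axes, indexing="ij")
    coded = np.column_stack([g.ravel() for g in grids])
    mask = np.ones(coded.shape[0], dtype=bool)
    for name, comp, threshold in constraints:
        pred = by_response[name].predict_coded(coded)
        mask &= _COMPARATORS[comp](pred, threshold)
    return DesignSpace(
        factors=list(factors),
        axes=axes,
        mask=mask.reshape([grid_resolution] * len(factors)),
        constraints=list(constraints),
    )


def feasible_at(
    models: Sequence[QuadraticModel],
    constraints: Sequence[tuple[str, str, float]],
    actual_settings: Mapping[str, float] | Sequence[float],
) -> bool:
    """Check the constraint set directly at one actual-units point."""
    by_response = {m.response_name: m for m in models}
    for name, comp, threshold in constraints:
        pred = by_response[name].predict(actual_settings)
        if not _COMPARATORS[comp](pred, threshold):
            return False
    return True
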