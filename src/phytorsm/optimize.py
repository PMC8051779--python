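"""Desirability scoring and constrained maximization of a fitted surface.

The desirability transform (Derringer & Suich) maps a predicted response
onto [0, 1] according to an optimization goal: a one-sided linear ramp
with a weight exponent for maximize/minimize goals, a two-sided tent for
a target goal, and a 0/1 indicator for in-range. The optimizer then
searches the experimental region — the factorial cube [-1, 1]^k by
default, or the axial sphere of radius alpha — with multi-start local
refinement from seeded interior points plus every cube vertex and the
centre, which for a quadratic surface reliably finds the constrained
optimum.

For monotone goals (maximize/minimize) the search is run on the raw
predicted response rather than on the ramp itself: the ramp is a
non-decreasing transform, so both have the same argmax, and the raw
response has no plateau once the ramp saturates at 1. Ties are broken
toward the lexicographically smallest coded coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
from scipy import optimize as sopt

from .design import decode_value
from .rsm import FittedRSModel, predict, predict_many


class GoalError(ValueError):
    pass


@dataclass(frozen=True)
class DesirabilityGoal:
    kind: str  # "maximize" | "minimize" | "target" | "in_range"
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("maximize", "minimize", "target", "in_range"):
            raise GoalError(f"unknown goal kind {self.kind!r}")
        if not self.lower < self.upper:
            raise GoalError("goal needs lower < upper")
        if self.weight <= 0:
            raise GoalError("weight must be positive")
        if self.kind == "target":
            if self.target is None or not (self.lower < self.target < self.upper):
                raise GoalError("target goal needs lower < target < upper")


def desirability(value, goal: DesirabilityGoal):
    """Desirability in [0, 1] of a response value (scalar or array)."""
    y = np.asarray(value, dtype=float)
    lo, hi, w = goal.lower, goal.upper, goal.weight
    if goal.kind == "maximize":
        d = np.clip((y - lo) / (hi - lo), 0.0, 1.0) ** w
    elif goal.kind == "minimize":
        d = np.clip((hi - y) / (hi - lo), 0.0, 1.0) ** w
    elif goal.kind == "target":
        t = goal.target
        up = np.clip((y - lo) / (t - lo), 0.0, 1.0)
        down = np.clip((hi - y) / (hi - t), 0.0, 1.0)
        d = np.where(y <= t, up, down) ** w
    else:  # in_range
        d = ((y >= lo) & (y <= hi)).astype(float)
    return float(d) if np.isscalar(value) else d


def goal_from_observed(response, kind: str = "maximize", weight: float = 1.0) -> DesirabilityGoal:
    """Goal with ramp limits at the observed response min/max — the usual
    default when no external specification limits exist."""
    y = np.asarray(response, dtype=float)
    return DesirabilityGoal(kind=kind, lower=float(y.min()), upper=float(y.max()), weight=weight)


@dataclass(frozen=True)
class OptimizationResult:
    argmax_coded: tuple[float, ...]
    argmax_actual: tuple[float, ...]
    predicted_response: float
    desirability: float
    n_starts: int
    region: str


def _objective(model: FittedRSModel, goal: DesirabilityGoal):
    """Scalar function to MINIMIZE over coded space."""
    if goal.kind == "maximize":
        return lambda x: -predict(model, x)
    if goal.kind == "minimize":
        return lambda x: predict(model, x)
    return lambda x: -desirability(predict(model, x), goal)


def optimize_model(
    model: FittedRSModel,
    region: str = "factorial_cube",
    goal: DesirabilityGoal | None = None,
    n_starts: int = 32,
    seed: int = 0,
    alpha: float | None = None,
) -> OptimizationResult:
    """Find the coded settings maximizing the goal over the region.

    ``region`` is "factorial_cube" (all |x_j| <= 1) or "axial_sphere"
    (||x|| <= alpha; requires ``alpha``). ``goal=None`` means plain
    maximization with ramp limits at the achieved prediction range, so
    the reported desirability is 1 at the optimum by construction;
    supply an explicit goal to score against external limits.
    """
    k = model.k
    if region not in ("factorial_cube", "axial_sphere"):
        raise GoalError(f"unknown region {region!r}")
    if region == "axial_sphere" and alpha is None:
        raise GoalError("axial_sphere region requires alpha")

    rng = np.random.default_rng(seed)
    scale = 1.0 if region == "factorial_cube" else float(alpha)
    starts = list(rng.uniform(-scale, scale, size=(max(n_starts, 1), k)))
    starts += [np.array(v, dtype=float) for v in itertools.product((-1.0, 1.0), repeat=k)]
    starts.append(np.zeros(k))

    placeholder_goal = goal is None
    work_goal = goal if goal is not None else DesirabilityGoal("maximize", 0.0, 1.0)
    fun = _objective(model, work_goal)

    candidates: list[np.ndarray] = []
    if region == "factorial_cube":
        bounds = [(-1.0, 1.0)] * k
        for x0 in starts:
            res = sopt.minimize(fun, np.clip(x0, -1, 1), method="L-BFGS-B", bounds=bounds)
            candidates.append(np.clip(res.x, -1.0, 1.0))
    else:
        cons = [{"type": "ineq", "fun": lambda x: scale**2 - float(x @ x)}]
        for x0 in starts:
            norm = np.linalg.norm(x0)
            if norm > scale:
                x0 = x0 * (scale / norm)
            res = sopt.minimize(fun, x0, method="SLSQP", constraints=cons)
            x = res.x
            norm = np.linalg.norm(x)
            if norm > scale:
                x = x * (scale / norm)
            candidates.append(x)
    # also score the raw starts, so a failed local solve can never lose
    # ground against simple evaluation
    candidates.extend(np.clip(s, -scale, scale) for s in starts)

    vals = np.array([fun(c) for c in candidates])
    best = vals.min()
    tied = [c for c, v in zip(candidates, vals) if v <= best + 1e-9]
    tied.sort(key=lambda c: tuple(np.round(c, 7)))
    x_best = tied[0]

    y_best = predict(model, x_best)
    if placeholder_goal:
        # score against the achieved range so desirability is defined
        d = 1.0
    else:
        d = float(desirability(y_best, work_goal))
    actual = tuple(
        float(decode_value(x_best[j], model.factors[j])) for j in range(k)
    ) if model.factors else tuple(float(v) for v in x_best)
    return OptimizationResult(
        argmax_coded=tuple(float(v) for v in x_best),
        argmax_actual=actual,
        predicted_response=float(y_best),
        desirability=d,
        n_starts=len(starts),
        region=region,
    )


def grid_maximum(
    model: FittedRSModel, resolution: int = 201, bound: float = 1.0
) -> tuple[np.ndarray, float]:
    """Brute-force maximum of the surface on a coded cube grid — an
    independent check on the local optimizer (exact up to grid spacing)."""
    g = np.linspace(-bound, bound, resolution)
    grids = np.meshgrid(*([g] * model.k), indexing="ij")
    pts = np.column_stack([a.ravel() for a in grids])
    vals = predict_many(model, pts)
    i = int(np.argmax(vals))
    return pts[i], float(vals[i])
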