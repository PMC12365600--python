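"""Multi-response desirability optimization over the constrained simplex.

Each fitted response gets a Derringer–Suich desirability goal mapping a raw
prediction to [0, 1] (maximize / minimize / target / in-range, with a ramp
exponent ``weight``), and candidates are ranked by the overall desirability
``D = (prod d_i**r_i)**(1/sum r_i)`` where ``r_i`` is the per-goal importance
(1–5).  Desirability is always evaluated on the *raw* response scale, so a
negative transform exponent (nMFI is modeled on ``Y**-1.5``) cannot invert a
goal's direction.

The search seeds a multistart Nelder–Mead from the best points of a
candidate set (vertices, centroids and interior points of the feasible
region), with components that are held fixed — e.g. the ionizable lipid and
PEG-lipid molar fractions pinned at their optimum — removed from the search
space.  Free components are reparameterized by dropping one coordinate; the
repair step clips to bounds and renormalizes so every evaluated point is a
feasible mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import ComponentBounds, Design, build_candidate_set
from .exceptions import GoalError, InfeasibleError, PredictionDomainError
from .models import FittedModel, predict_response

__all__ = [
    "Goal",
    "Candidate",
    "OptimizationResult",
    "desirability_value",
    "overall_desirability",
    "optimize_formulation",
    "rank_candidates",
]


@dataclass(frozen=True)
class Goal:
    """A desirability target for one response.

    ``low``/``target``/``high`` are on the raw response scale; ``weight`` is
    the ramp exponent (w > 1 demands values close to the target before
    rewarding them); ``importance`` (1–5) is the exponent in the overall
    geometric mean.
    """

    response: str
    direction: str                 # maximize | minimize | target | in_range
    low: float | None = None
    target: float | None = None
    high: float | None = None
    weight: float = 1.0
    importance: int = 3

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize", "target", "in_range"):
            raise GoalError(f"unknown goal direction {self.direction!r}")
        if self.weight <= 0:
            raise GoalError("weight must be positive")
        if not (isinstance(self.importance, (int, np.integer)) and 1 <= self.importance <= 5):
            raise GoalError("importance must be an integer in [1, 5]")
        if self.direction == "maximize":
            if self.low is None or self.target is None or not self.low < self.target:
                raise GoalError("maximize goal needs low < target")
        elif self.direction == "minimize":
            if self.target is None or self.high is None or not self.target < self.high:
                raise GoalError("minimize goal needs target < high")
        elif self.direction == "target":
            ok = (
                self.low is not None
                and self.target is not None
                and self.high is not None
                and self.low < self.target < self.high
            )
            if not ok:
                raise GoalError("target goal needs low < target < high")
        else:  # in_range
            if self.low is None or self.high is None or not self.low < self.high:
                raise GoalError("in_range goal needs low < high")


def desirability_value(y: float | np.ndarray, goal: Goal) -> np.ndarray:
    """Derringer–Suich desirability of raw response value(s) under a goal."""
    y = np.asarray(y, dtype=float)
    w = goal.weight
    if goal.direction == "maximize":
        lo, tg = goal.low, goal.target
        d = np.clip((y - lo) / (tg - lo), 0.0, 1.0) ** w
    elif goal.direction == "minimize":
        tg, hi = goal.target, goal.high
        d = np.clip((hi - y) / (hi - tg), 0.0, 1.0) ** w
    elif goal.direction == "target":
        lo, tg, hi = goal.low, goal.target, goal.high
        up = np.clip((y - lo) / (tg - lo), 0.0, 1.0) ** w
        down = np.clip((hi - y) / (hi - tg), 0.0, 1.0) ** w
        d = np.where(y <= tg, up, down)
    else:  # in_range
        d = ((goal.low <= y) & (y <= goal.high)).astype(float)
    return d if d.shape else float(d)


def overall_desirability(
    d: Sequence[float] | np.ndarray, importances: Sequence[float] | np.ndarray
) -> float:
    """Importance-weighted geometric mean ``(prod d_i**r_i)**(1/sum r_i)``."""
    d = np.asarray(d, dtype=float)
    r = np.asarray(importances, dtype=float)
    if d.size == 0:
        raise GoalError("overall desirability needs at least one goal")
    if d.shape != r.shape:
        raise ValueError("desirabilities and importances differ in length")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("per-goal desirabilities must lie in [0, 1]")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(r * np.log(d)) / np.sum(r)))


@dataclass
class Candidate:
    composition: dict[str, float]
    responses: dict[str, float]
    desirabilities: dict[str, float]
    overall: float


@dataclass
class OptimizationResult:
    """Candidates ranked by overall desirability (descending)."""

    candidates: list[Candidate]
    names: tuple[str, ...]
    n_starts: int
    seed: int | None

    @property
    def best(self) -> Candidate:
        return self.candidates[0]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {f"x_{k}": v for k, v in c.composition.items()}
            row.update({f"pred_{k}": v for k, v in c.responses.items()})
            row.update({f"d_{k}": v for k, v in c.desirabilities.items()})
            row["desirability"] = c.overall
            rows.append(row)
        return pd.DataFrame(rows)


def _evaluate(
    x: np.ndarray,
    names: tuple[str, ...],
    models: Mapping[str, FittedModel],
    goals: Sequence[Goal],
) -> Candidate:
    responses: dict[str, float] = {}
    desir: dict[str, float] = {}
    ds = []
    for goal in goals:
        model = models[goal.response]
        try:
            pred = float(predict_response(model, x[None, :])[0])
        except PredictionDomainError:
            # no raw-scale image: the goal cannot be met there
            responses[goal.response] = np.nan
            desir[goal.response] = 0.0
            ds.append(0.0)
            continue
        responses[goal.response] = pred
        d = float(desirability_value(pred, goal))
        desir[goal.response] = d
        ds.append(d)
    overall = overall_desirability(ds, [g.importance for g in goals])
    return Candidate(dict(zip(names, x)), responses, desir, overall)


def optimize_formulation(
    models: Mapping[str, FittedModel],
    goals: Sequence[Goal],
    bounds: ComponentBounds,
    fixed: Mapping[str, float] | None = None,
    n_starts: int = 50,
    seed: int | None = 0,
    n_top: int = 5,
    n_interior: int = 200,
) -> OptimizationResult:
    """Maximize overall desirability over the feasible mixture region.

    ``fixed`` pins named components at exact proportions; the remaining
    components are optimized over the sub-simplex that keeps the total at
    one.  Candidate-set seeding plus multistart Nelder–Mead; the returned
    top-``n_top`` candidates are distinct local optima ranked by overall
    desirability, and the best one is never worse than any seeding point.
    """
    goals = list(goals)
    if not goals:
        raise GoalError("at least one goal is required")
    for goal in goals:
        if goal.response not in models:
            raise KeyError(f"goal response {goal.response!r} has no fitted model")
    fixed = dict(fixed or {})
    names = bounds.names
    unknown = set(fixed) - set(names)
    if unknown:
        raise InfeasibleError(f"fixed components {sorted(unknown)} not in bounds")
    fixed_total = sum(fixed.values())
    free = [i for i, nm in enumerate(names) if nm not in fixed]
    if not free:
        raise InfeasibleError("every component is fixed; nothing to optimize")
    remainder = 1.0 - fixed_total
    if remainder <= 0:
        raise InfeasibleError(
            f"fixed components sum to {fixed_total:.4f} >= 1"
        )
    for nm, v in fixed.items():
        j = names.index(nm)
        if not (bounds.lower[j] - 1e-12 <= v <= bounds.upper[j] + 1e-12):
            raise InfeasibleError(
                f"fixed {nm}={v} violates its bounds "
                f"[{bounds.lower[j]}, {bounds.upper[j]}]"
            )

    # Feasible region of the free components, rescaled to a unit simplex.
    sub_lo = [min(bounds.lower[i] / remainder, 1.0) for i in free]
    sub_hi = [min(bounds.upper[i] / remainder, 1.0) for i in free]
    sub_bounds = ComponentBounds(
        tuple(names[i] for i in free), tuple(sub_lo), tuple(sub_hi)
    )
    rng = np.random.default_rng(seed)
    cand = build_candidate_set(sub_bounds, n_interior=n_interior, seed=rng)

    def assemble(u: np.ndarray) -> np.ndarray:
        x = np.empty(len(names))
        for nm, v in fixed.items():
            x[names.index(nm)] = v
        x[free] = u * remainder
        return x

    sub_lo_arr = np.asarray(sub_bounds.lower)
    sub_hi_arr = np.asarray(sub_bounds.upper)

    def repair(v: np.ndarray) -> np.ndarray:
        """Project k-1 unconstrained coords onto the bounded sub-simplex.

        Bisection on the shift ``t`` in ``clip(u - t, lo, hi)`` until the
        coordinates sum to one — the exact Euclidean-style projection onto
        the box-constrained simplex, so every evaluated point is feasible.
        """
        u = np.append(v, 1.0 - v.sum())
        t_lo = float((u - sub_hi_arr).min())
        t_hi = float((u - sub_lo_arr).max())
        for _ in range(100):
            t_mid = 0.5 * (t_lo + t_hi)
            s = np.clip(u - t_mid, sub_lo_arr, sub_hi_arr).sum()
            if s > 1.0:
                t_lo = t_mid
            else:
                t_hi = t_mid
        out = np.clip(u - 0.5 * (t_lo + t_hi), sub_lo_arr, sub_hi_arr)
        # distribute any residual rounding over the interior coordinates
        slack = 1.0 - out.sum()
        if slack != 0.0:
            room = (
                np.minimum(sub_hi_arr - out, slack)
                if slack > 0
                else np.maximum(sub_lo_arr - out, slack)
            )
            movable = np.abs(room) > 0
            if movable.any():
                out[movable] += slack * np.abs(room[movable]) / np.abs(room[movable]).sum()
        return out

    def neg_d(v: np.ndarray) -> float:
        return -_evaluate(assemble(repair(v)), names, models, goals).overall

    cand_scores = np.array(
        [
            _evaluate(assemble(u), names, models, goals).overall
            for u in cand.compositions
        ]
    )
    order = np.argsort(-cand_scores, kind="stable")
    starts = order[: max(1, min(n_starts, len(order)))]

    pool: list[Candidate] = []
    for s in starts:
        v0 = cand.compositions[s][:-1]
        res = minimize(
            neg_d,
            v0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        u = repair(res.x)
        pool.append(_evaluate(assemble(u), names, models, goals))
    # seeding points themselves stay in the pool so the reported optimum can
    # never fall below the best candidate
    for s in starts:
        pool.append(_evaluate(assemble(cand.compositions[s]), names, models, goals))

    pool.sort(
        key=lambda c: (-c.overall, tuple(c.composition.values()))
    )
    distinct: list[Candidate] = []
    for c in pool:
        xs = np.array(list(c.composition.values()))
        if all(
            np.max(np.abs(xs - np.array(list(d.composition.values())))) > 1e-4
            for d in distinct
        ):
            distinct.append(c)
        if len(distinct) >= n_top:
            break
    if distinct and distinct[0].overall == 0.0:
        warnings.warn(
            "overall desirability is zero everywhere searched; at least one "
            "goal is unmet across the region",
            stacklevel=2,
        )
    return OptimizationResult(
        candidates=distinct,
        names=names,
        n_starts=len(starts),
        seed=seed if isinstance(seed, int) else None,
    )


def rank_candidates(result: OptimizationResult, key: str = "D") -> OptimizationResult:
    """Reorder candidates by a predicted response (descending) or by ``D``.

    Stable sort; ties are broken by overall desirability, then by
    lexicographic composition.  Ranking by predicted nMFI is how the final
    formulation is picked from a candidate list.
    """
    if key in ("D", "desirability"):
        ordered = sorted(
            result.candidates,
            key=lambda c: (-c.overall, tuple(c.composition.values())),
        )
    else:
        if not result.candidates:
            ordered = []
        elif key not in result.candidates[0].responses:
            raise KeyError(f"unknown ranking key {key!r}")
        else:
            ordered = sorted(
                result.candidates,
                key=lambda c: (
                    -c.responses[key],
                    -c.overall,
                    tuple(c.composition.values()),
                ),
            )
    return OptimizationResult(
        candidates=list(ordered),
        names=result.names,
        n_starts=result.n_starts,
        seed=result.seed,
    )
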