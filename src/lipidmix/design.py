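"""Constrained mixture designs and exchange-based optimal design construction.

A mixture experiment varies the proportions ``x_1..x_q`` of the components of
a blend under the simplex constraint ``sum(x_i) = 1``, usually with extra box
bounds ``l_i <= x_i <= u_i`` per component.  For lipid nanoparticles the four
components are the helper phospholipid (DSPC), the ionizable lipid (SM-102),
cholesterol and the PEG-lipid (DMG-PEG2000), expressed as molar fractions.

This module provides:

* :class:`ComponentBounds` / :class:`Design` — the design region and design
  matrix containers;
* :class:`ModelSpec` — a Scheffé canonical polynomial term set (no intercept;
  linear blending terms ``x_i`` and binary blending terms ``x_i x_j``);
* candidate-set construction (extreme vertices, edge centroids, overall
  centroid, uniform interior fill);
* the I- and D-optimality criteria and a Fedorov-style point-exchange
  optimizer over a candidate set;
* small utilities: point-wise prediction variance, design validation, and
  constant-ratio design series (e.g. a DSPC/cholesterol ratio sweep with the
  ionizable and PEG lipids held fixed).

The I-criterion is ``trace((X'X)^-1 M)`` with ``M = E[f(x) f(x)']`` the moment
matrix of the model expansion over the feasible region; minimizing it
minimizes the region-averaged scaled prediction variance.  The D-criterion is
``-log det(X'X)``.  Both are *minimized* here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    DomainError,
    InfeasibleError,
    RegionEmptyError,
    SamplingFailureError,
    SingularInformationError,
    UnderDeterminedError,
)

__all__ = [
    "ComponentBounds",
    "Design",
    "ModelSpec",
    "OptimalityReport",
    "ViolationReport",
    "build_candidate_set",
    "moment_matrix",
    "design_criterion",
    "exchange_design",
    "prediction_variance",
    "validate_design",
    "ratio_series",
    "sample_region",
]

_ROW_SUM_TOL = 1e-9
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class ComponentBounds:
    """Box bounds on each mixture component, defining a constrained simplex.

    Parameters
    ----------
    names
        Component identifiers, e.g. ``("DSPC", "SM-102", "cholesterol",
        "DMG-PEG2000")``.
    lower, upper
        Per-component proportion limits on the 0–1 scale.
    """

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        lo = tuple(float(v) for v in self.lower)
        hi = tuple(float(v) for v in self.upper)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if not (len(names) == len(lo) == len(hi)):
            raise ValueError("names, lower and upper must have equal length")
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        for name, a, b in zip(names, lo, hi):
            if not (0.0 <= a < b <= 1.0):
                raise ValueError(
                    f"component {name!r}: require 0 <= lower < upper <= 1, "
                    f"got [{a}, {b}]"
                )
        if sum(lo) > 1.0 + _BOUND_TOL or sum(hi) < 1.0 - _BOUND_TOL:
            raise RegionEmptyError(
                f"bounds give empty region: sum(lower)={sum(lo):.4f}, "
                f"sum(upper)={sum(hi):.4f}"
            )

    @property
    def q(self) -> int:
        return len(self.names)

    def contains(self, x: np.ndarray, tol: float = _BOUND_TOL) -> np.ndarray:
        """Boolean mask of rows of ``x`` inside the bounds (sum not checked)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((x >= lo - tol) & (x <= hi + tol), axis=1)


@dataclass
class Design:
    """An ``n x q`` matrix of mixture compositions (proportions, rows sum to 1).

    ``is_validation`` flags hold-out runs that must be excluded from model
    fitting (the Spikevax-ratio run MS in the built-in design).
    """

    compositions: np.ndarray
    names: tuple[str, ...]
    run_ids: tuple[str, ...] = ()
    is_validation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.compositions = np.atleast_2d(
            np.asarray(self.compositions, dtype=float)
        )
        self.names = tuple(self.names)
        n, q = self.compositions.shape
        if q != len(self.names):
            raise ValueError("column count does not match component names")
        if not self.run_ids:
            self.run_ids = tuple(f"R{i + 1:02d}" for i in range(n))
        else:
            self.run_ids = tuple(str(r) for r in self.run_ids)
        if len(self.run_ids) != n:
            raise ValueError("run_ids length does not match row count")
        if self.is_validation is None:
            self.is_validation = np.zeros(n, dtype=bool)
        else:
            self.is_validation = np.asarray(self.is_validation, dtype=bool)
        sums = self.compositions.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if np.any(bad):
            first = int(np.argmax(bad))
            raise ValueError(
                f"design row {self.run_ids[first]!r} sums to "
                f"{sums[first]:.6f}, not 1"
            )

    @property
    def n(self) -> int:
        return self.compositions.shape[0]

    @property
    def q(self) -> int:
        return self.compositions.shape[1]

    def modeling_rows(self) -> "Design":
        """The sub-design with validation runs removed."""
        keep = ~self.is_validation
        return Design(
            self.compositions[keep],
            self.names,
            tuple(np.asarray(self.run_ids)[keep]),
            self.is_validation[keep],
        )

    def validation_rows(self) -> "Design":
        keep = self.is_validation
        if not np.any(keep):
            raise ValueError("design has no validation rows")
        return Design(
            self.compositions[keep],
            self.names,
            tuple(np.asarray(self.run_ids)[keep]),
            self.is_validation[keep],
        )


@dataclass(frozen=True)
class ModelSpec:
    """An ordered Scheffé canonical polynomial term set.

    Each term is a tuple of component indices: size 1 is a linear blending
    term ``x_i``, size 2 a binary blending term ``x_i x_j``.  There is no
    intercept — with all linear terms present the constant is spanned because
    the proportions sum to one.
    """

    terms: tuple[tuple[int, ...], ...]
    q: int

    def __post_init__(self) -> None:
        terms = tuple(tuple(sorted(int(i) for i in t)) for t in self.terms)
        object.__setattr__(self, "terms", terms)
        if len(terms) < 1:
            raise ValueError("a model needs at least one term")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in model spec")
        for t in terms:
            if len(t) not in (1, 2):
                raise ValueError(f"term {t} must have 1 or 2 indices")
            if any(i < 0 or i >= self.q for i in t):
                raise ValueError(f"term {t} has index outside [0, {self.q})")

    @property
    def p(self) -> int:
        return len(self.terms)

    @classmethod
    def linear(cls, q: int) -> "ModelSpec":
        return cls(tuple((i,) for i in range(q)), q)

    @classmethod
    def quadratic(cls, q: int) -> "ModelSpec":
        terms = [(i,) for i in range(q)]
        terms += list(itertools.combinations(range(q), 2))
        return cls(tuple(tuple(t) for t in terms), q)

    def matrix(self, x: np.ndarray) -> np.ndarray:
        """Model matrix: column ``j`` is the product of the term-``j`` components."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.q:
            raise ValueError(
                f"compositions have {x.shape[1]} columns, spec expects {self.q}"
            )
        cols = [np.prod(x[:, list(t)], axis=1) for t in self.terms]
        return np.column_stack(cols)

    def term_labels(self, names: Sequence[str] | None = None) -> tuple[str, ...]:
        if names is None:
            # classic mixture shorthand A, B, C, ...
            names = [chr(ord("A") + i) for i in range(self.q)]
        return tuple("*".join(names[i] for i in t) for t in self.terms)

    def is_hierarchical(self) -> bool:
        """True if every component in a pair term also appears as a linear term."""
        singles = {t[0] for t in self.terms if len(t) == 1}
        return all(
            set(t) <= singles for t in self.terms if len(t) == 2
        )


@dataclass
class OptimalityReport:
    """Bookkeeping for one exchange-design run."""

    criterion: str
    value: float
    n_iterations: int
    n_starts: int
    best_start: int
    start_values: tuple[float, ...]
    initial_values: tuple[float, ...] = ()


@dataclass
class ViolationReport:
    """Per-run constraint violations found by :func:`validate_design`."""

    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthiness == validity
        return self.ok


# ---------------------------------------------------------------------------
# Region sampling and candidate sets
# ---------------------------------------------------------------------------

def sample_region(
    bounds: ComponentBounds,
    n: int,
    rng: np.random.Generator,
    min_acceptance: float = 1e-4,
) -> np.ndarray:
    """Draw ``n`` uniform points from the bounded simplex by rejection.

    Proposals are uniform on the unconstrained simplex (flat Dirichlet) and
    kept if they satisfy the box bounds.  Raises
    :class:`SamplingFailureError` when the empirical acceptance rate falls
    below ``min_acceptance`` — a sign that the bounds carve out a sliver of
    the simplex and a specialised sampler (hit-and-run) would be needed.
    """
    q = bounds.q
    out: list[np.ndarray] = []
    got = 0
    proposed = 0
    batch = max(4 * n, 1000)
    while got < n:
        draw = rng.dirichlet(np.ones(q), size=batch)
        proposed += batch
        keep = draw[bounds.contains(draw)]
        if keep.size:
            out.append(keep)
            got += keep.shape[0]
        if proposed >= 10 * batch and got / proposed < min_acceptance:
            raise SamplingFailureError(
                f"rejection acceptance rate {got / proposed:.2e} below "
                f"{min_acceptance:.0e}; loosen the bounds or use a "
                "specialised sampler"
            )
    return np.vstack(out)[:n]


def _extreme_vertices(bounds: ComponentBounds) -> np.ndarray:
    """Extreme vertices of the bounded simplex.

    Classic enumeration: fix ``q - 1`` components at lower/upper bound
    combinations, solve the remaining (fill) component from the sum-to-one
    constraint, and keep the point when the fill value respects its own
    bounds.
    """
    q = bounds.q
    lo = np.asarray(bounds.lower)
    hi = np.asarray(bounds.upper)
    pts = []
    for fill in range(q):
        others = [i for i in range(q) if i != fill]
        for combo in itertools.product(*[(lo[i], hi[i]) for i in others]):
            x = np.empty(q)
            x[others] = combo
            x[fill] = 1.0 - sum(combo)
            if lo[fill] - _BOUND_TOL <= x[fill] <= hi[fill] + _BOUND_TOL:
                pts.append(np.clip(x, lo, hi))
    if not pts:
        raise RegionEmptyError("no extreme vertex satisfies the bounds")
    return _dedupe(np.array(pts))


def _dedupe(points: np.ndarray, decimals: int = 9) -> np.ndarray:
    rounded = np.round(points, decimals)
    _, idx = np.unique(rounded, axis=0, return_index=True)
    return points[np.sort(idx)]


def build_candidate_set(
    bounds: ComponentBounds,
    n_interior: int = 50,
    seed: int | np.random.Generator = 0,
) -> Design:
    """Candidate points for exchange search on a bounded simplex.

    The set is the union of the extreme vertices, the midpoint of every
    vertex pair (edge centroids), the overall vertex centroid, and
    ``n_interior`` uniform interior points, deduplicated.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vertices = _extreme_vertices(bounds)
    parts = [vertices]
    if len(vertices) > 1:
        mids = [
            (vertices[i] + vertices[j]) / 2.0
            for i, j in itertools.combinations(range(len(vertices)), 2)
        ]
        parts.append(np.array(mids))
    parts.append(vertices.mean(axis=0, keepdims=True))
    if n_interior > 0:
        parts.append(sample_region(bounds, n_interior, rng))
    pts = _dedupe(np.vstack(parts))
    pts = pts / pts.sum(axis=1, keepdims=True)  # kill bound-clipping drift
    ids = tuple(f"C{i + 1:03d}" for i in range(len(pts)))
    return Design(pts, bounds.names, ids)


# ---------------------------------------------------------------------------
# Optimality criteria
# ---------------------------------------------------------------------------

def moment_matrix(
    bounds: ComponentBounds,
    spec: ModelSpec,
    n_mc: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte-Carlo region moment matrix ``M = E[f(x) f(x)']``.

    Averaged over ``n_mc`` uniform points of the bounded simplex.  The exact
    matrix is symmetric positive semidefinite; the estimate is symmetrized
    to make that hold to the last bit.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000 for a usable estimate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = sample_region(bounds, n_mc, rng)
    f = spec.matrix(pts)
    m = f.T @ f / n_mc
    return (m + m.T) / 2.0


def _information(design_x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    f = spec.matrix(design_x)
    return f.T @ f


def _criterion_from_info(
    xtx: np.ndarray, which: str, m: np.ndarray | None
) -> float:
    """Criterion value, ``inf`` when X'X is singular (internal, never raises)."""
    if which == "D":
        sign, logdet = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        return -logdet
    try:
        c = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        return np.inf
    sol = np.linalg.solve(c.T, np.linalg.solve(c, m))
    return float(np.trace(sol))


def design_criterion(
    design: Design | np.ndarray,
    spec: ModelSpec,
    which: str = "I",
    M: np.ndarray | None = None,
) -> float:
    """I- or D-optimality criterion of a design (both minimized).

    ``I = trace((X'X)^-1 M)`` — the average scaled prediction variance over
    the region whose moment matrix is ``M``.  ``D = -log det(X'X)``.
    """
    which = which.upper()
    if which not in ("I", "D"):
        raise ValueError("criterion must be 'I' or 'D'")
    x = design.compositions if isinstance(design, Design) else np.asarray(design)
    if x.shape[0] < spec.p:
        raise UnderDeterminedError(
            f"{x.shape[0]} runs cannot support {spec.p} coefficients"
        )
    if which == "I":
        if M is None:
            raise ValueError("the I-criterion needs a region moment matrix M")
        if M.shape != (spec.p, spec.p):
            raise ValueError("moment matrix dimension does not match the spec")
    xtx = _information(x, spec)
    value = _criterion_from_info(xtx, which, M)
    if not np.isfinite(value):
        raise SingularInformationError(
            f"X'X is singular for terms {spec.term_labels()}"
        )
    return value


def prediction_variance(
    design: Design | np.ndarray, spec: ModelSpec, x: np.ndarray
) -> float:
    """Scaled prediction variance ``f(x)' (X'X)^-1 f(x)`` at one composition."""
    dx = design.compositions if isinstance(design, Design) else np.asarray(design)
    xtx = _information(dx, spec)
    f = spec.matrix(np.atleast_2d(x))[0]
    try:
        c = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError as err:
        raise SingularInformationError(
            f"X'X is singular for terms {spec.term_labels()}"
        ) from err
    w = np.linalg.solve(c, f)
    return float(w @ w)


# ---------------------------------------------------------------------------
# Point exchange
# ---------------------------------------------------------------------------

def exchange_design(
    bounds: ComponentBounds,
    spec: ModelSpec,
    n_runs: int,
    which: str = "I",
    candidates: Design | None = None,
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
    M: np.ndarray | None = None,
    rel_tol: float = 1e-8,
    max_passes: int = 200,
) -> tuple[Design, OptimalityReport]:
    """Fedorov-style point exchange over a candidate set.

    From each random start (``n_runs`` candidates drawn with replacement) the
    algorithm repeatedly tries replacing every design point with every
    candidate, accepts the swap with the largest criterion decrease, and
    stops when no swap improves by more than ``rel_tol`` relatively.  Ties
    are broken toward the lowest (row, candidate) index pair, so the result
    is deterministic given the seed.  The best design across starts is
    returned.
    """
    which = which.upper()
    if n_runs < spec.p:
        raise UnderDeterminedError(
            f"n_runs={n_runs} is below the {spec.p} model coefficients"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if candidates is None:
        candidates = build_candidate_set(bounds, seed=rng)
    if candidates.n == 0:
        raise ValueError("candidate set is empty")
    if which == "I" and M is None:
        M = moment_matrix(bounds, spec, seed=rng)

    fc = spec.matrix(candidates.compositions)  # m x p, reused throughout
    m_cand = fc.shape[0]

    def crit(idx: np.ndarray) -> float:
        x = fc[idx]
        return _criterion_from_info(x.T @ x, which, M)

    best_idx: np.ndarray | None = None
    best_val = np.inf
    best_start = -1
    total_iters = 0
    start_vals: list[float] = []
    init_vals: list[float] = []

    for s in range(n_starts):
        idx = rng.choice(m_cand, size=n_runs, replace=n_runs > m_cand)
        cur = crit(idx)
        init_vals.append(cur)
        for _ in range(max_passes):
            best_swap = None
            best_new = cur
            for i in range(n_runs):
                saved = idx[i]
                for j in range(m_cand):
                    if j == saved:
                        continue
                    idx[i] = j
                    v = crit(idx)
                    if v < best_new - rel_tol * max(1.0, abs(cur)):
                        best_new = v
                        best_swap = (i, j)
                idx[i] = saved
            if best_swap is None:
                break
            idx[best_swap[0]] = best_swap[1]
            cur = best_new
            total_iters += 1
        start_vals.append(cur)
        if cur < best_val:
            best_val = cur
            best_idx = idx.copy()
            best_start = s

    if best_idx is None or not np.isfinite(best_val):
        raise SingularInformationError(
            "every start produced a singular information matrix; "
            "enlarge the candidate set or reduce the model"
        )
    x_best = candidates.compositions[np.sort(best_idx)]
    design = Design(
        x_best,
        candidates.names,
        tuple(f"X{i + 1:02d}" for i in range(n_runs)),
    )
    report = OptimalityReport(
        criterion=which,
        value=best_val,
        n_iterations=total_iters,
        n_starts=n_starts,
        best_start=best_start,
        start_values=tuple(start_vals),
        initial_values=tuple(init_vals),
    )
    return design, report


# ---------------------------------------------------------------------------
# Validation and derived designs
# ---------------------------------------------------------------------------

def validate_design(
    design: Design,
    bounds: ComponentBounds | None = None,
    sum_tol: float = 1e-6,
    bound_tol: float = 1e-9,
) -> ViolationReport:
    """Report per-run sum-to-one and bound violations (empty report = valid)."""
    msgs: list[str] = []
    sums = design.compositions.sum(axis=1)
    for i, rid in enumerate(design.run_ids):
        if abs(sums[i] - 1.0) > sum_tol:
            msgs.append(f"{rid}: row sums to {sums[i]:.6f}, not 1")
        if bounds is not None:
            for j, name in enumerate(bounds.names):
                v = design.compositions[i, j]
                if v < bounds.lower[j] - bound_tol or v > bounds.upper[j] + bound_tol:
                    msgs.append(
                        f"{rid}: {name} = {v:.4f} outside "
                        f"[{bounds.lower[j]}, {bounds.upper[j]}]"
                    )
    return ViolationReport(tuple(msgs))


def ratio_series(
    names: Sequence[str],
    fixed: Mapping[str, float],
    pair: tuple[str, str],
    ratios: Iterable[float],
    run_prefix: str = "N",
) -> Design:
    """Designs sweeping the ratio of two components with the rest held fixed.

    The remainder ``r = 1 - sum(fixed)`` is split between the pair so that
    ``first / second = ratio``: ``first = r * ratio / (1 + ratio)``,
    ``second = r / (1 + ratio)``.  One run per ratio.  This is how a
    DSPC-to-cholesterol storage-stability series is built with the ionizable
    lipid and PEG-lipid molar fractions pinned at their optimum.
    """
    names = tuple(names)
    if set(fixed) | set(pair) != set(names) or set(fixed) & set(pair):
        raise ValueError("fixed components plus the pair must partition names")
    total_fixed = sum(fixed.values())
    if not 0.0 < total_fixed < 1.0:
        raise InfeasibleError(
            f"fixed components sum to {total_fixed:.4f}; need a value in (0, 1)"
        )
    ratios = [float(r) for r in ratios]
    if any(r <= 0 for r in ratios):
        raise DomainError("ratios must be strictly positive")
    remainder = 1.0 - total_fixed
    rows = []
    for r in ratios:
        x = dict(fixed)
        x[pair[0]] = remainder * r / (1.0 + r)
        x[pair[1]] = remainder / (1.0 + r)
        rows.append([x[nm] for nm in names])
    ids = tuple(f"{run_prefix}{i + 1}" for i in range(len(rows)))
    return Design(np.array(rows), names, ids)
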