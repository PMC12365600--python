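"""Sequential sums of squares and BIC stepwise selection of Scheffé terms.

Term screening follows the response-surface workflow: candidate binary
blending terms are ordered and scored by their sequential (type-I) sum of
squares — the incremental SSE drop when each term enters in the stated
order — and the working model is then chosen by BIC, either by forward
selection from the mandatory linear blending terms or by backward
elimination from a full candidate model.  The BIC is the Gaussian profile
form ``n ln(SSE/n) + k ln(n)`` with ``k`` the number of coefficients.

Mixture hierarchy is enforced structurally: the linear blending terms are
mandatory (never removed), so any set of binary terms yields a hierarchical
model.  :func:`exhaustive_best_subset` enumerates every hierarchy-valid
subset and serves as the oracle the stepwise procedures are tested against.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import Design, ModelSpec
from .exceptions import UnderDeterminedError
from .models import TransformSpec, _training_arrays

__all__ = [
    "SelectionTrace",
    "StepRecord",
    "sequential_ss",
    "bic_score",
    "forward_select",
    "backward_eliminate",
    "exhaustive_best_subset",
    "stepwise_select",
]

Term = tuple[int, ...]


@dataclass(frozen=True)
class StepRecord:
    action: str          # "start", "add", "remove"
    term: Term | None
    sse: float
    k: int
    bic_before: float
    bic_after: float


@dataclass
class SelectionTrace:
    """Ordered record of a stepwise run; BIC never increases across steps."""

    direction: str
    steps: tuple[StepRecord, ...]
    final_spec: ModelSpec
    final_sse: float
    final_bic: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "action": [s.action for s in self.steps],
                "term": [
                    "" if s.term is None else "x".join(map(str, s.term))
                    for s in self.steps
                ],
                "sse": [s.sse for s in self.steps],
                "k": [s.k for s in self.steps],
                "bic_before": [s.bic_before for s in self.steps],
                "bic_after": [s.bic_after for s in self.steps],
            }
        )


def bic_score(n: int, sse: float, k: int) -> float:
    """Gaussian profile BIC: ``n ln(SSE/n) + k ln(n)``.

    Constant terms of the Gaussian likelihood are dropped — only BIC
    differences matter for selection.  A perfect fit (SSE = 0) maps to
    ``-inf`` with a warning rather than an error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sse < 0:
        raise ValueError("SSE cannot be negative")
    if sse == 0:
        warnings.warn("perfect fit: BIC is -inf", stacklevel=2)
        return -np.inf
    return n * np.log(sse / n) + k * np.log(n)


def _norm_terms(terms: Sequence[Term]) -> tuple[Term, ...]:
    return tuple(tuple(sorted(t)) for t in terms)


def _sse_and_rank(x: np.ndarray, t: np.ndarray) -> tuple[float, int]:
    """SSE of the least-squares projection of ``t`` on ``x`` (rank-robust)."""
    beta, _, rank, _ = np.linalg.lstsq(x, t, rcond=None)
    resid = t - x @ beta
    return float(resid @ resid), int(rank)


def _prepare(
    design: Design,
    y: np.ndarray,
    transform: TransformSpec,
) -> tuple[np.ndarray, np.ndarray]:
    xd, yv, _ = _training_arrays(design, y)
    return xd, transform.apply(yv)


def sequential_ss(
    design: Design,
    y: np.ndarray,
    transform: TransformSpec,
    ordered_terms: Sequence[Term],
    base_terms: Sequence[Term] | None = None,
) -> pd.DataFrame:
    """Type-I (sequential) sum-of-squares table for an ordered term list.

    Each term's SS is the SSE drop when it enters after everything before
    it.  The base model is the grand mean unless ``base_terms`` is given, so
    the increments plus the final SSE telescope to the mean-corrected total
    sum of squares.  A term that adds no rank (collinear with what is
    already in) is reported as a zero-df step with SS ≈ 0.  F statistics
    test each increment against the final model's MSE and are descriptive
    (no multiplicity correction).
    """
    xd, t = _prepare(design, y, transform)
    n = t.shape[0]
    q = xd.shape[1]
    ordered_terms = _norm_terms(ordered_terms)
    cols = [np.ones((n, 1))]
    if base_terms:
        base_spec = ModelSpec(_norm_terms(base_terms), q)
        cols.append(base_spec.matrix(xd))
    x = np.hstack(cols)
    sse_prev, rank_prev = _sse_and_rank(x, t)
    rows = []
    for term in ordered_terms:
        col = np.prod(xd[:, list(term)], axis=1)[:, None]
        x = np.hstack([x, col])
        sse, rank = _sse_and_rank(x, t)
        rows.append(
            {
                "term": "x".join(map(str, term)),
                "ss": max(sse_prev - sse, 0.0),
                "df": rank - rank_prev,
            }
        )
        sse_prev, rank_prev = sse, rank
    sse_final, rank_final = sse_prev, rank_prev
    df_resid = n - rank_final
    mse = sse_final / df_resid if df_resid > 0 else np.nan
    table = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["F"] = np.where(
            table["df"] > 0, (table["ss"] / table["df"].replace(0, np.nan)) / mse, np.nan
        )
    table["p_value"] = stats.f.sf(table["F"], table["df"], df_resid)
    table.attrs["sse_residual"] = sse_final
    table.attrs["df_residual"] = df_resid
    return table


# ---------------------------------------------------------------------------
# Stepwise search
# ---------------------------------------------------------------------------

def _fit_sse(xd: np.ndarray, t: np.ndarray, terms: tuple[Term, ...], q: int) -> float:
    spec = ModelSpec(terms, q)
    sse, _ = _sse_and_rank(spec.matrix(xd), t)
    return sse


def _sse_floor(t: np.ndarray) -> float:
    """Numerical floor for SSE in BIC comparisons.

    A noiseless fit leaves an SSE at rounding-error level; its logarithm then
    jitters by more than the ``ln n`` parsimony penalty and elimination stalls
    on noise.  Flooring SSE at a relative 1e-12 of the corrected total sum of
    squares makes all essentially-perfect models tie on the likelihood term,
    so BIC resolves them by term count alone.
    """
    sst = float(((t - t.mean()) ** 2).sum())
    return 1e-12 * max(sst, 1.0)


def _check_start(n: int, k: int, what: str) -> None:
    if n <= k:
        raise UnderDeterminedError(
            f"{what} model has {k} coefficients for {n} runs; "
            "no residual degrees of freedom"
        )


def forward_select(
    design: Design,
    y: np.ndarray,
    transform: TransformSpec,
    candidate_terms: Sequence[Term],
    mandatory_terms: Sequence[Term] | None = None,
) -> SelectionTrace:
    """Forward BIC selection from the mandatory (default: all linear) terms.

    At each step the candidate term with the largest BIC decrease enters;
    the search stops when no addition lowers BIC.  Because the linear
    blending terms stay in the model, the result is always hierarchy-valid.
    """
    xd, t = _prepare(design, y, transform)
    n, q = xd.shape
    if mandatory_terms is None:
        mandatory_terms = [(i,) for i in range(q)]
    current = _norm_terms(mandatory_terms)
    pool = [t_ for t_ in _norm_terms(candidate_terms) if t_ not in current]
    _check_start(n, len(current), "mandatory")
    floor = _sse_floor(t)
    sse = _fit_sse(xd, t, current, q)
    bic = bic_score(n, max(sse, floor), len(current))
    steps = [StepRecord("start", None, sse, len(current), bic, bic)]
    while pool:
        best = None
        for term in pool:
            trial = current + (term,)
            if n <= len(trial):
                continue
            sse_t = _fit_sse(xd, t, trial, q)
            bic_t = bic_score(n, max(sse_t, floor), len(trial))
            if bic_t < bic and (best is None or bic_t < best[1]):
                best = (term, bic_t, sse_t)
        if best is None:
            break
        term, bic_new, sse_new = best
        steps.append(StepRecord("add", term, sse_new, len(current) + 1, bic, bic_new))
        current = current + (term,)
        pool.remove(term)
        bic, sse = bic_new, sse_new
    spec = ModelSpec(current, q)
    return SelectionTrace("forward", tuple(steps), spec, sse, bic)


def backward_eliminate(
    design: Design,
    y: np.ndarray,
    transform: TransformSpec,
    full_terms: Sequence[Term],
    mandatory_terms: Sequence[Term] | None = None,
) -> SelectionTrace:
    """Backward BIC elimination from a full candidate model.

    Repeatedly drops the non-mandatory term whose removal most decreases
    BIC, stopping when every removal would raise it.
    """
    xd, t = _prepare(design, y, transform)
    n, q = xd.shape
    current = _norm_terms(full_terms)
    if mandatory_terms is None:
        mandatory_terms = [(i,) for i in range(q)]
    mandatory = set(_norm_terms(mandatory_terms))
    if n <= len(current):
        raise UnderDeterminedError(
            f"full model has {len(current)} coefficients for {n} runs; "
            "start from a smaller model (forward selection)"
        )
    floor = _sse_floor(t)
    sse = _fit_sse(xd, t, current, q)
    bic = bic_score(n, max(sse, floor), len(current))
    steps = [StepRecord("start", None, sse, len(current), bic, bic)]
    while True:
        removable = [t_ for t_ in current if t_ not in mandatory]
        best = None
        for term in removable:
            trial = tuple(t_ for t_ in current if t_ != term)
            sse_t = _fit_sse(xd, t, trial, q)
            bic_t = bic_score(n, max(sse_t, floor), len(trial))
            if bic_t < bic and (best is None or bic_t < best[1]):
                best = (term, bic_t, sse_t)
        if best is None:
            break
        term, bic_new, sse_new = best
        steps.append(
            StepRecord("remove", term, sse_new, len(current) - 1, bic, bic_new)
        )
        current = tuple(t_ for t_ in current if t_ != term)
        bic, sse = bic_new, sse_new
    spec = ModelSpec(current, q)
    return SelectionTrace("backward", tuple(steps), spec, sse, bic)


def exhaustive_best_subset(
    design: Design,
    y: np.ndarray,
    transform: TransformSpec,
    candidate_terms: Sequence[Term],
    mandatory_terms: Sequence[Term] | None = None,
    max_terms: int | None = None,
) -> ModelSpec:
    """BIC-optimal hierarchy-valid subset by enumeration (test oracle).

    Ties are broken toward fewer terms, then lexicographic term order.
    Refuses problems with more than ``2**20`` subsets.
    """
    xd, t = _prepare(design, y, transform)
    n, q = xd.shape
    if mandatory_terms is None:
        mandatory_terms = [(i,) for i in range(q)]
    mandatory = _norm_terms(mandatory_terms)
    pool = [t_ for t_ in _norm_terms(candidate_terms) if t_ not in mandatory]
    if 2 ** len(pool) > 2 ** 20:
        raise ValueError(
            f"{len(pool)} free terms give {2 ** len(pool)} subsets; too many"
        )
    limit = len(pool) if max_terms is None else min(
        len(pool), max_terms - len(mandatory)
    )
    best: tuple[float, int, tuple[Term, ...], tuple[Term, ...]] | None = None
    for r in range(limit + 1):
        for extra in itertools.combinations(pool, r):
            terms = mandatory + extra
            if n <= len(terms):
                continue
            sse = _fit_sse(xd, t, terms, q)
            bic = bic_score(n, max(sse, _sse_floor(t)), len(terms))
            key = (bic, len(terms), tuple(sorted(extra)))
            if best is None or key < (best[0], best[1], best[3]):
                best = (bic, len(terms), terms, tuple(sorted(extra)))
    if best is None:
        raise UnderDeterminedError("no subset leaves residual degrees of freedom")
    return ModelSpec(best[2], q)


def stepwise_select(
    design: Design,
    y: np.ndarray,
    transform: TransformSpec,
    candidate_terms: Sequence[Term],
    mandatory_terms: Sequence[Term] | None = None,
    direction: str = "both",
) -> SelectionTrace:
    """Run forward and/or backward selection; with ``both``, the lower-BIC
    model wins and exact ties favor the one with fewer terms."""
    if direction == "forward":
        return forward_select(design, y, transform, candidate_terms, mandatory_terms)
    if direction == "backward":
        xd, _ = _prepare(design, y, transform)
        full = _norm_terms(candidate_terms)
        mand = (
            _norm_terms(mandatory_terms)
            if mandatory_terms is not None
            else tuple((i,) for i in range(xd.shape[1]))
        )
        full = tuple(dict.fromkeys(mand + tuple(t for t in full if t not in mand)))
        return backward_eliminate(design, y, transform, full, mandatory_terms)
    if direction != "both":
        raise ValueError("direction must be forward, backward or both")
    fwd = forward_select(design, y, transform, candidate_terms, mandatory_terms)
    try:
        bwd = stepwise_select(
            design, y, transform, candidate_terms, mandatory_terms, "backward"
        )
    except UnderDeterminedError:
        return fwd
    if (bwd.final_bic, bwd.final_spec.p) < (fwd.final_bic, fwd.final_spec.p):
        return bwd
    return fwd
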