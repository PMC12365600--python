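"""Power transforms, Scheffé polynomial fitting and adequacy statistics.

Responses from a formulation screen — encapsulation efficiency (%), particle
diameter (nm), normalized median fluorescence intensity (nMFI, fold over
untreated control) — are modeled on a power-transformed scale ``t = y**λ``
(``ln y`` at λ = 0).  The transform exponent is chosen by a Box–Cox profile
log-likelihood scan against the design's model matrix, then snapped to a
"convenient" value (−2, −1.5, −1, −0.5, 0, 0.5, 1, 2) inside the ~95%
confidence interval, which is how response-surface software reports it.

Models are canonical Scheffé polynomials fitted by ordinary least squares
(statsmodels OLS, no intercept: the linear blending terms span the constant
on a mixture).  Fit adequacy follows the response-surface conventions:

* ``R²``, adjusted ``R²`` on the mean-corrected total sum of squares,
* ``PRESS = Σ (e_i / (1 - h_ii))²`` and predicted ``R² = 1 - PRESS/SST``,
* ``CV% = 100·√MSE / mean``,
* adequate precision ``(max ŷ - min ŷ) / sqrt(p·MSE/n)`` — a signal-to-noise
  ratio, acceptable above 4,
* the over-fit screen: adjusted ``R²`` minus predicted ``R²`` below 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import Design, ModelSpec
from .exceptions import (
    DomainError,
    PredictionDomainError,
    SingularInformationError,
    UnderDeterminedError,
    ValidationLeakageError,
)

__all__ = [
    "TransformSpec",
    "FittedModel",
    "FitStats",
    "AdequacyFlags",
    "BoxCoxScan",
    "normalize_mfi",
    "power_transform",
    "inverse_power",
    "boxcox_scan",
    "choose_convenient_lambda",
    "scheffe_matrix",
    "fit_scheffe",
    "fit_statistics",
    "adequacy_check",
    "predict_response",
    "holdout_validation",
    "CONVENIENT_LAMBDAS",
]

CONVENIENT_LAMBDAS = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


def normalize_mfi(mfi_treated: float, mfi_control: float) -> float:
    """nMFI: median fluorescence of treated cells over the untreated control."""
    if mfi_control <= 0:
        raise DomainError("control MFI must be strictly positive")
    return float(mfi_treated) / float(mfi_control)


# ---------------------------------------------------------------------------
# Power transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformSpec:
    """A plain power transform ``t = y**λ`` with ``λ = 0`` meaning ``ln y``."""

    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise ValueError("transform exponent must be finite")

    def apply(self, y: np.ndarray) -> np.ndarray:
        return power_transform(y, self.lam)

    def invert(self, t: np.ndarray) -> np.ndarray:
        return inverse_power(t, self.lam)

    def label(self) -> str:
        return "ln(Y)" if self.lam == 0 else f"Y^{self.lam:g}"


def _needs_positive(lam: float) -> bool:
    return lam <= 0 or not float(lam).is_integer()


def power_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """``y**λ`` elementwise (``ln y`` at λ = 0), guarding the domain."""
    y = np.asarray(y, dtype=float)
    if _needs_positive(lam) and np.any(y <= 0):
        raise DomainError(
            f"power transform with λ={lam:g} requires strictly positive values"
        )
    if lam == 0:
        return np.log(y)
    return np.power(y, lam)


def inverse_power(t: np.ndarray, lam: float) -> np.ndarray:
    """Inverse of :func:`power_transform`: ``t**(1/λ)`` (``exp`` at λ = 0)."""
    t = np.asarray(t, dtype=float)
    if lam == 0:
        return np.exp(t)
    if _needs_positive(1.0 / lam) and np.any(t <= 0):
        raise DomainError(
            f"inverse power with λ={lam:g} requires strictly positive values"
        )
    return np.power(t, 1.0 / lam)


# ---------------------------------------------------------------------------
# Box–Cox profile likelihood
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxScan:
    """Profile log-likelihood of the Box–Cox exponent over a grid."""

    lambdas: np.ndarray
    loglik: np.ndarray
    best_lambda: float
    ci_lower: float
    ci_upper: float

    def in_ci(self, lam: float) -> bool:
        return self.ci_lower <= lam <= self.ci_upper


def boxcox_scan(
    y: np.ndarray,
    X: np.ndarray,
    lambdas: np.ndarray | None = None,
    conf_level: float = 0.95,
    ci_method: str = "t",
) -> BoxCoxScan:
    """Scan the Box–Cox exponent by profile log-likelihood against ``X``.

    Uses the geometric-mean-normalized transform
    ``z(λ) = (y**λ - 1) / (λ g**(λ-1))`` (``g ln y`` at λ = 0, ``g`` the
    geometric mean), regresses ``z`` on the supplied model matrix by least
    squares, and scores ``λ`` by ``-(n/2) ln(SSE_λ / n)``.  The normalization
    makes log-likelihoods comparable across ``λ`` and the whole curve
    invariant to rescaling ``y`` by a positive constant.

    The ~``conf_level`` confidence interval is the set of grid points whose
    log-likelihood stays within a cut of the maximum.  ``ci_method="t"``
    (default) calibrates the cut by the exact Gaussian small-sample ratio,
    ``(n/2)·ln(1 + t²(α/2, ν)/ν)`` with ``ν = n - rank(X)`` — the SSE-ratio
    interval response-surface software draws, which holds its coverage at
    the handful-of-runs sizes mixture screens use.  ``ci_method="chisq"``
    uses the asymptotic ``χ²₁(conf_level)/2`` cut, which is anti-
    conservative when ``ν`` is small.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise DomainError("Box–Cox scan requires strictly positive responses")
    if lambdas is None:
        lambdas = np.linspace(-3.0, 3.0, 121)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.min() > -3.0 or lambdas.max() < 3.0:
        raise ValueError("the λ grid must cover at least [-3, 3]")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    g = np.exp(np.mean(np.log(y)))
    ll = np.empty(lambdas.shape)
    for k, lam in enumerate(lambdas):
        if lam == 0:
            z = g * np.log(y)
        else:
            z = (np.power(y, lam) - 1.0) / (lam * g ** (lam - 1.0))
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
        sse = float(resid @ resid)
        ll[k] = -0.5 * n * np.log(max(sse, 1e-300) / n)
    kbest = int(np.argmax(ll))
    if ci_method == "chisq":
        drop = stats.chi2.ppf(conf_level, df=1) / 2.0
    elif ci_method == "t":
        nu = n - int(np.linalg.matrix_rank(X))
        if nu <= 0:
            raise ValueError("no residual degrees of freedom for the CI")
        tq = stats.t.ppf(1.0 - (1.0 - conf_level) / 2.0, df=nu)
        drop = 0.5 * n * np.log1p(tq ** 2 / nu)
    else:
        raise ValueError("ci_method must be 't' or 'chisq'")
    cut = ll[kbest] - drop
    inside = lambdas[ll >= cut]
    return BoxCoxScan(
        lambdas=lambdas,
        loglik=ll,
        best_lambda=float(lambdas[kbest]),
        ci_lower=float(inside.min()),
        ci_upper=float(inside.max()),
    )


def choose_convenient_lambda(
    scan: BoxCoxScan,
    convenient: Sequence[float] = CONVENIENT_LAMBDAS,
) -> TransformSpec:
    """Snap the scanned exponent to the nearest convenient value in the CI.

    If no convenient value falls inside the confidence interval the nearest
    one overall is returned with a warning — the fit then uses an exponent
    the data only marginally support.
    """
    convenient = sorted(convenient)
    in_ci = [c for c in convenient if scan.in_ci(c)]
    pool = in_ci if in_ci else convenient
    if not in_ci:
        warnings.warn(
            "no convenient Box–Cox exponent falls inside the confidence "
            f"interval [{scan.ci_lower:.2f}, {scan.ci_upper:.2f}]; "
            "using the nearest convenient value",
            stacklevel=2,
        )
    best = min(pool, key=lambda c: (abs(c - scan.best_lambda), c))
    return TransformSpec(best)


# ---------------------------------------------------------------------------
# Scheffé OLS
# ---------------------------------------------------------------------------

def scheffe_matrix(design: Design | np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Scheffé canonical model matrix (no intercept column)."""
    x = design.compositions if isinstance(design, Design) else np.asarray(design)
    return spec.matrix(x)


@dataclass
class FittedModel:
    """An OLS fit of a transformed response on a Scheffé term set."""

    spec: ModelSpec
    transform: TransformSpec
    coef: np.ndarray
    fitted: np.ndarray            # transformed scale
    residuals: np.ndarray
    hat: np.ndarray
    sse: float
    n: int
    p: int
    run_ids: tuple[str, ...]
    response_name: str = ""
    component_names: tuple[str, ...] = ()

    @property
    def mse(self) -> float:
        return self.sse / (self.n - self.p)

    @property
    def transformed_observed(self) -> np.ndarray:
        return self.fitted + self.residuals

    def equation(self, decimals: int = 2) -> str:
        """Human-readable fitted equation in A/B/C/... mixture shorthand."""
        labels = self.spec.term_labels()
        parts = []
        for c, lab in zip(self.coef, labels):
            sign = "-" if c < 0 else "+"
            parts.append(f"{sign} {abs(c):.{decimals}f} {lab}")
        text = " ".join(parts)
        return text[2:] if text.startswith("+ ") else text


def _training_arrays(
    design: Design, y: np.ndarray | pd.Series
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Align a response vector to the design and drop hold-out rows."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n:
        raise ValueError(
            f"response has {y.shape[0]} values for a {design.n}-run design"
        )
    keep = ~design.is_validation
    ids = tuple(np.asarray(design.run_ids)[keep])
    return design.compositions[keep], y[keep], ids


def fit_scheffe(
    design: Design,
    y: np.ndarray | pd.Series,
    spec: ModelSpec,
    transform: TransformSpec = TransformSpec(1.0),
    response_name: str = "",
) -> FittedModel:
    """OLS of the power-transformed response on the Scheffé model matrix.

    Rows flagged ``is_validation`` in the design are excluded from the fit,
    so a hold-out run can never leak into training.
    """
    xd, yv, ids = _training_arrays(design, y)
    t = transform.apply(yv)
    X = spec.matrix(xd)
    n, p = X.shape
    if n <= p:
        raise UnderDeterminedError(
            f"{n} modeling runs cannot estimate {p} coefficients with "
            "residual degrees of freedom"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularInformationError(
            f"model matrix is rank deficient for terms {spec.term_labels()}"
        )
    res = sm.OLS(t, X).fit()
    hat = res.get_influence().hat_matrix_diag
    return FittedModel(
        spec=spec,
        transform=transform,
        coef=np.asarray(res.params, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        hat=np.asarray(hat, dtype=float),
        sse=float(res.ssr),
        n=n,
        p=p,
        run_ids=ids,
        response_name=response_name,
        component_names=tuple(design.names),
    )


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------

@dataclass
class AdequacyFlags:
    """Adequacy screens of a response-surface fit."""

    r2_gap_ok: bool          # adjusted R² − predicted R² < 0.2
    adequate_precision_ok: bool   # adequate precision > 4

    @property
    def passed(self) -> bool:
        return self.r2_gap_ok and self.adequate_precision_ok


@dataclass
class FitStats:
    """Response-surface summary statistics on the transformed scale."""

    std_dev: float
    mean: float
    cv_pct: float
    r2: float
    adj_r2: float
    press: float
    pred_r2: float
    adequate_precision: float
    press_defined: bool = True

    def adequacy(self) -> AdequacyFlags:
        return adequacy_check(self)


def fit_statistics(model: FittedModel) -> FitStats:
    """R², adjusted/predicted R², PRESS, CV% and adequate precision.

    All on the transformed scale the model was fitted on.  The total sum of
    squares is mean-corrected even though the model has no intercept: the
    Scheffé linear terms span the constant on a mixture, so the corrected
    SST is the right yardstick.  PRESS uses the leave-one-out shortcut
    ``e_i / (1 - h_ii)``; a leverage of exactly one makes the shortcut (and
    LOO itself) undefined, flagged via ``press_defined``.
    """
    t = model.transformed_observed
    n, p = model.n, model.p
    tbar = float(t.mean())
    sst = float(((t - tbar) ** 2).sum())
    sse = model.sse
    mse = model.mse
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (sse / (n - p)) / (sst / (n - 1))
    at_one = np.isclose(model.hat, 1.0, atol=1e-10)
    press_defined = not bool(at_one.any())
    if press_defined:
        press = float(((model.residuals / (1.0 - model.hat)) ** 2).sum())
        pred_r2 = 1.0 - press / sst
    else:
        press = np.nan
        pred_r2 = np.nan
    std_dev = float(np.sqrt(mse))
    cv_pct = 100.0 * std_dev / tbar if tbar != 0 else np.inf
    spread = float(model.fitted.max() - model.fitted.min())
    if mse == 0:
        adeq = np.inf
    else:
        adeq = spread / float(np.sqrt(p * mse / n))
    return FitStats(
        std_dev=std_dev,
        mean=tbar,
        cv_pct=cv_pct,
        r2=r2,
        adj_r2=adj_r2,
        press=press,
        pred_r2=pred_r2,
        adequate_precision=adeq,
        press_defined=press_defined,
    )


def adequacy_check(stats: FitStats) -> AdequacyFlags:
    """Apply the two standard adequacy screens.

    A fit is considered usable for navigating the design space when the
    adjusted-minus-predicted R² gap is below 0.2 (no over-fit) and the
    adequate precision (signal-to-noise) exceeds 4.
    """
    gap_ok = bool((stats.adj_r2 - stats.pred_r2) < 0.2)
    ap_ok = bool(stats.adequate_precision > 4.0)
    return AdequacyFlags(r2_gap_ok=gap_ok, adequate_precision_ok=ap_ok)


# ---------------------------------------------------------------------------
# Prediction and hold-out validation
# ---------------------------------------------------------------------------

def predict_response(
    model: FittedModel, compositions: Design | np.ndarray
) -> np.ndarray:
    """Raw-scale predictions at new compositions.

    The linear predictor lives on the transformed scale and is mapped back
    through the inverse power.  With a negative exponent the map is strictly
    decreasing (a smaller transformed value is a larger raw response), and a
    non-positive transformed prediction has no raw-scale image — that raises
    :class:`PredictionDomainError` naming the offending composition.
    """
    x = (
        compositions.compositions
        if isinstance(compositions, Design)
        else np.atleast_2d(np.asarray(compositions, dtype=float))
    )
    t_pred = model.spec.matrix(x) @ model.coef
    lam = model.transform.lam
    # a fractional or negative exponent has no raw-scale image for t <= 0
    if lam != 0 and (lam < 0 or not float(lam).is_integer()):
        bad = t_pred <= 0
        if np.any(bad):
            i = int(np.argmax(bad))
            raise PredictionDomainError(
                f"transformed prediction {t_pred[i]:.4g} at composition "
                f"{np.round(x[i], 4).tolist()} cannot be inverted with "
                f"λ={lam:g}"
            )
    return model.transform.invert(t_pred)


def holdout_validation(
    model: FittedModel,
    holdout: Design,
    y_holdout: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Predicted-vs-observed table for hold-out runs.

    Refuses to score a run whose ``run_id`` was part of the training set
    (that would be validation leakage, not validation).
    """
    y_holdout = np.asarray(y_holdout, dtype=float)
    if y_holdout.shape[0] != holdout.n:
        raise ValueError("hold-out responses do not match the hold-out design")
    overlap = set(holdout.run_ids) & set(model.run_ids)
    if overlap:
        raise ValidationLeakageError(
            f"hold-out runs {sorted(overlap)} were in the training design"
        )
    pred = predict_response(model, holdout)
    abs_err = np.abs(pred - y_holdout)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(y_holdout != 0, abs_err / np.abs(y_holdout), np.nan)
    return pd.DataFrame(
        {
            "run_id": list(holdout.run_ids),
            "observed": y_holdout,
            "predicted": pred,
            "abs_error": abs_err,
            "rel_error": rel_err,
        }
    )
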