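"""Built-in S-type LNP study objects and synthetic response generation.

Ships, as package data, the 16-run I-optimal mixture design of the S-type
(Spikevax-composition) LNP screen — 15 modeling runs M01–M15 plus the
hold-out run MS at the commercial molar ratios 10/50/38.5/1.5 — together
with the three published fitted response models:

==========================  =========  ==============================================
response                    transform  fitted equation (proportion scale)
==========================  =========  ==============================================
encapsulation efficiency E  Y^1        57.77 A + 62.05 B + 106.35 C − 177.89 D
diameter G                  Y^0.5      25.87 A + 9.12 B + 4.22 C − 77.48 D
                                       − 21.14 AB + 12.29 BC + 49.40 BD + 117.57 CD
nMFI F                      Y^−1.5     −0.15 A + 0.30 B + 0.45 C + 5.61 D + 1.67 AC
==========================  =========  ==============================================

with A = DSPC, B = SM-102, C = cholesterol, D = DMG-PEG2000 and residual
standard deviations 14.31, 1.56 and 0.0961 on the respective transformed
scales.

The response generator draws Gaussian noise around the model predictions on
the *transformed* scale — the scale the analysis assumes the noise lives
on — and maps back through the inverse power.  Draws whose raw-scale image
is impossible (encapsulation outside (0, 100], diameter or nMFI not
positive) are redrawn and counted, so the marginal distributions are
truncated normals with an explicit, logged truncation rate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import ComponentBounds, Design, ModelSpec
from .exceptions import GenerationError
from .models import TransformSpec, inverse_power

__all__ = [
    "GroundTruth",
    "COMPONENTS",
    "RESPONSES",
    "REPORTED_FIT_STATS",
    "builtin_bounds",
    "builtin_design",
    "builtin_models",
    "simulate_responses",
    "simulate_boxcox_dataset",
]

COMPONENTS = ("DSPC", "SM-102", "cholesterol", "DMG-PEG2000")
RESPONSES = ("encapsulation_pct", "diameter_nm", "nmfi")

_DESIGN_SHA256 = "f44406af728f33fc46527ef442ecf7051d444d158ba9a0fc2e6fc21579a035d7"

#: Published summary statistics of the three fits (transformed scale):
#: std_dev, mean, CV%, R², adjusted R², predicted R², adequate precision.
REPORTED_FIT_STATS: dict[str, dict[str, float]] = {
    "encapsulation_pct": {
        "std_dev": 14.31, "mean": 59.49, "cv_pct": 24.06,
        "r2": 0.6273, "adj_r2": 0.5987, "pred_r2": 0.5139,
        "adequate_precision": 16.84,
    },
    "diameter_nm": {
        "std_dev": 1.56, "mean": 8.83, "cv_pct": 17.65,
        "r2": 0.8127, "adj_r2": 0.7686, "pred_r2": 0.6752,
        "adequate_precision": 18.27,
    },
    "nmfi": {
        "std_dev": 0.0961, "mean": 0.769, "cv_pct": 12.5,
        "r2": 0.9085, "adj_r2": 0.8902, "pred_r2": 0.8491,
        "adequate_precision": 19.82,
    },
}


@dataclass(frozen=True)
class GroundTruth:
    """A generating model: term set, coefficients, transform, residual SD."""

    response: str
    spec: ModelSpec
    coef: np.ndarray
    transform: TransformSpec
    sigma: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "coef", coef)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if coef.shape[0] != self.spec.p:
            raise ValueError("coefficient count does not match the term set")
        if not np.all(np.isfinite(coef)):
            raise ValueError("coefficients must be finite")
        if not self.spec.is_hierarchical():
            raise ValueError("generating model must be hierarchy-valid")

    def transformed_mean(self, design: Design | np.ndarray) -> np.ndarray:
        x = design.compositions if isinstance(design, Design) else np.asarray(design)
        return self.spec.matrix(x) @ self.coef


def builtin_bounds() -> ComponentBounds:
    """Molar-fraction ranges of the S-type screen: DSPC 5–40%, SM-102 and
    cholesterol 15–65%, DMG-PEG2000 1–10%."""
    return ComponentBounds(
        names=COMPONENTS,
        lower=(0.05, 0.15, 0.15, 0.01),
        upper=(0.40, 0.65, 0.65, 0.10),
    )


def builtin_design() -> Design:
    """The 15-run I-optimal design plus the MS hold-out, as proportions.

    Loaded from the packaged CSV (percent scale, checksummed) and divided
    by 100.
    """
    path = resources.files("lipidmix.data").joinpath("design_s_type.csv")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DESIGN_SHA256:
        raise RuntimeError(
            "packaged design fixture is corrupted "
            f"(sha256 {digest} != {_DESIGN_SHA256})"
        )
    df = pd.read_csv(path)
    comps = df[list(COMPONENTS)].to_numpy(dtype=float) / 100.0
    return Design(
        compositions=comps,
        names=COMPONENTS,
        run_ids=tuple(df["run_id"]),
        is_validation=df["is_validation"].to_numpy(dtype=bool),
    )


def builtin_models() -> dict[str, GroundTruth]:
    """The three published fitted models keyed by response column name."""
    q = 4
    e = GroundTruth(
        response="encapsulation_pct",
        spec=ModelSpec(((0,), (1,), (2,), (3,)), q),
        coef=np.array([57.77, 62.05, 106.35, -177.89]),
        transform=TransformSpec(1.0),
        sigma=14.31,
    )
    g = GroundTruth(
        response="diameter_nm",
        spec=ModelSpec(
            ((0,), (1,), (2,), (3,), (0, 1), (1, 2), (1, 3), (2, 3)), q
        ),
        coef=np.array([25.87, 9.12, 4.22, -77.48, -21.14, 12.29, 49.40, 117.57]),
        transform=TransformSpec(0.5),
        sigma=1.56,
    )
    f = GroundTruth(
        response="nmfi",
        spec=ModelSpec(((0,), (1,), (2,), (3,), (0, 2)), q),
        coef=np.array([-0.15, 0.30, 0.45, 5.61, 1.67]),
        transform=TransformSpec(-1.5),
        sigma=0.0961,
    )
    return {t.response: t for t in (e, g, f)}


# Raw-scale validity windows used by the redraw policy.
_RAW_WINDOWS = {
    "encapsulation_pct": (0.0, 100.0),
    "diameter_nm": (0.0, np.inf),
    "nmfi": (0.0, np.inf),
}
_MAX_REDRAW_FACTOR = 0.5   # generation error above 50% rejected draws


def _draw_column(
    truth: GroundTruth,
    mu: np.ndarray,
    rng: np.random.Generator,
    window: tuple[float, float],
) -> tuple[np.ndarray, int]:
    """Truncated-normal draws on the transformed scale, mapped to raw."""
    lam = truth.transform.lam
    n = mu.shape[0]
    t = mu + rng.normal(0.0, truth.sigma, size=n)
    redraws = 0
    lo, hi = window

    def ok(tv: np.ndarray) -> np.ndarray:
        if lam != 0 and (lam < 0 or not float(lam).is_integer()):
            valid = tv > 0
        else:
            valid = np.isfinite(tv)
        raw = np.full_like(tv, np.nan)
        raw[valid] = inverse_power(tv[valid], lam)
        return valid & (raw > lo) & (raw <= hi)

    good = ok(t)
    attempts = 0
    while not good.all():
        bad = ~good
        redraws += int(bad.sum())
        t[bad] = mu[bad] + rng.normal(0.0, truth.sigma, size=int(bad.sum()))
        good = ok(t)
        attempts += 1
        if attempts > 1000 or redraws > _MAX_REDRAW_FACTOR * n * max(attempts, 1) and attempts > 10:
            raise GenerationError(
                f"response {truth.response!r}: systematic infeasibility, "
                f"{redraws} redraws for {n} values"
            )
    return inverse_power(t, lam), redraws


def simulate_responses(
    design: Design,
    truths: dict[str, GroundTruth] | None = None,
    seed: int | np.random.Generator = 0,
    n_rep: int = 1,
    truncate: bool = True,
) -> pd.DataFrame | list[pd.DataFrame]:
    """Synthetic response tables for a design (hold-out rows included).

    Per replicate and response: ``t = X beta + eps`` with
    ``eps ~ N(0, sigma^2)`` on the transformed scale, mapped back through
    the inverse power; out-of-window draws are redrawn (see module docs).
    The per-response redraw counts are stored in ``df.attrs['redraws']``.
    Fixed seed gives bit-identical output.

    With ``truncate=False`` the raw-scale window is not enforced and the
    transformed values are exactly Gaussian around the model surface — the
    sampling model under which OLS refits are unbiased.  Values whose raw
    image does not exist (non-positive transformed value under a negative
    or fractional exponent) are still redrawn.
    """
    truths = builtin_models() if truths is None else truths
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tables = []
    for _ in range(n_rep):
        df = pd.DataFrame({"run_id": list(design.run_ids)})
        redraws: dict[str, int] = {}
        for name, truth in truths.items():
            mu = truth.transformed_mean(design)
            window = (
                _RAW_WINDOWS.get(name, (0.0, np.inf))
                if truncate
                else (-np.inf, np.inf)
            )
            col, nredraw = _draw_column(truth, mu, rng, window)
            df[name] = col
            redraws[name] = nredraw
        df.attrs["redraws"] = redraws
        df.attrs["n_draws"] = design.n
        tables.append(df)
    return tables[0] if n_rep == 1 else tables


def simulate_boxcox_dataset(
    lam_true: float,
    beta: np.ndarray,
    sigma: float,
    design: Design,
    spec: ModelSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """A positive response vector generated on a known power scale.

    ``y = (X beta + eps)**(1/lam_true)`` (``exp`` at 0); draws whose inverse
    image would be non-positive are redrawn.  Used to check that the
    Box–Cox scan's confidence interval covers the generating exponent.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    truth = GroundTruth(
        response="synthetic",
        spec=spec,
        coef=np.asarray(beta, dtype=float),
        transform=TransformSpec(lam_true),
        sigma=float(sigma),
    )
    mu = truth.transformed_mean(design)
    y, _ = _draw_column(truth, mu, rng, (0.0, np.inf))
    return y
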