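"""CSV schemas, configuration and report writing for the formulation pipeline.

Design files are CSV with a ``run_id`` column, one column per component and
an optional ``is_validation`` flag.  Values may be percentages (rows summing
to about 100, the tabulation convention) or proportions (summing to about
1); the scale is auto-detected per file with a hard 1% consistency gate —
mixed or malformed files fail loudly rather than being silently rescaled.

Response files are CSV ``run_id,encapsulation_pct,diameter_nm,nmfi`` with
missing values allowed per cell; diameters and nMFI must be strictly
positive where present.

Reports mirror the standard response-surface presentation: a fitted-equation
block (coefficients to two decimals), a seven-column statistics table
(Std. dev., Mean, C.V. %, R², Adjusted R², Predicted R², Adequate
precision), adequacy flags and a ranked-candidate CSV.  Output is
deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import ComponentBounds, Design
from .exceptions import DomainError, MalformedRowError
from .models import FitStats, FittedModel
from .optimize import OptimizationResult
from .selection import SelectionTrace

__all__ = [
    "read_design",
    "write_design",
    "read_responses",
    "write_responses",
    "dilution_concentration",
    "full_factorial_size",
    "report",
    "RunConfig",
]

_REL_SUM_TOL = 0.01   # 1% gate for percent/proportion detection


def read_design(path: str | Path) -> Design:
    """Read a design CSV, auto-detecting percent vs proportion scale."""
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise MalformedRowError(f"{path}: missing 'run_id' column")
    comp_cols = [
        c for c in df.columns if c not in ("run_id", "is_validation")
    ]
    if not comp_cols:
        raise MalformedRowError(f"{path}: no component columns")
    x = df[comp_cols].to_numpy(dtype=float)
    sums = x.sum(axis=1)
    as_pct = np.abs(sums / 100.0 - 1.0) <= _REL_SUM_TOL
    as_prop = np.abs(sums - 1.0) <= _REL_SUM_TOL
    for i, rid in enumerate(df["run_id"]):
        if not (as_pct[i] or as_prop[i]):
            raise MalformedRowError(
                f"row {rid!r} sums to {sums[i]:.4f}: neither ~100 (percent) "
                "nor ~1 (proportion)"
            )
    if as_pct.all():
        x = x / 100.0
    elif not as_prop.all():
        raise MalformedRowError(
            "file mixes percent-scale and proportion-scale rows"
        )
    x = x / x.sum(axis=1, keepdims=True)
    is_val = (
        df["is_validation"].astype(float).to_numpy().astype(bool)
        if "is_validation" in df.columns
        else None
    )
    return Design(x, tuple(comp_cols), tuple(df["run_id"].astype(str)), is_val)


def write_design(design: Design, path: str | Path) -> None:
    """Write a design as percentages to 6 decimal places (round-trip safe)."""
    df = pd.DataFrame(
        np.round(design.compositions * 100.0, 6), columns=list(design.names)
    )
    df.insert(0, "run_id", list(design.run_ids))
    df["is_validation"] = design.is_validation.astype(int)
    df.to_csv(path, index=False, float_format="%.6f")


def read_responses(path: str | Path, design: Design) -> pd.DataFrame:
    """Read a response CSV and align it to a loaded design.

    Unknown run ids are a join error; non-positive diameter or nMFI cells
    are a domain error naming the cell.  Missing cells (empty/NaN) are
    allowed.
    """
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise MalformedRowError(f"{path}: missing 'run_id' column")
    df["run_id"] = df["run_id"].astype(str)
    known = set(design.run_ids)
    unknown = [r for r in df["run_id"] if r not in known]
    if unknown:
        raise KeyError(f"response rows reference unknown runs: {unknown}")
    dup = df["run_id"].duplicated()
    if dup.any():
        raise MalformedRowError(
            f"duplicate response rows for runs {sorted(set(df['run_id'][dup]))}"
        )
    for col in ("diameter_nm", "nmfi"):
        if col in df.columns:
            bad = df[col].notna() & (df[col] <= 0)
            if bad.any():
                rid = df.loc[bad, "run_id"].iloc[0]
                raise DomainError(
                    f"{col} must be positive; run {rid!r} has "
                    f"{df.loc[bad, col].iloc[0]}"
                )
    if "encapsulation_pct" in df.columns:
        bad = df["encapsulation_pct"].notna() & (
            (df["encapsulation_pct"] <= 0) | (df["encapsulation_pct"] > 100)
        )
        if bad.any():
            rid = df.loc[bad, "run_id"].iloc[0]
            raise DomainError(
                f"encapsulation_pct must lie in (0, 100]; run {rid!r} has "
                f"{df.loc[bad, 'encapsulation_pct'].iloc[0]}"
            )
    order = {r: i for i, r in enumerate(design.run_ids)}
    return df.sort_values("run_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def dilution_concentration(
    stock_pct: float, parts_stock: float, parts_diluent_suspension: float
) -> float:
    """Final % w/v after volumetric dilution of a stock.

    Mixing a cryoprotectant stock 1:1 (v/v) with an LNP suspension halves
    its concentration: a 40% sucrose stock gives 20% final.
    """
    if stock_pct < 0 or parts_stock < 0 or parts_diluent_suspension < 0:
        raise DomainError("volumes and concentrations must be non-negative")
    total = parts_stock + parts_diluent_suspension
    if total <= 0:
        raise DomainError("total volume parts must be positive")
    return stock_pct * parts_stock / total


def full_factorial_size(levels_per_factor: Sequence[int]) -> int:
    """Run count of a full factorial: the product of the level counts.

    Four factors at four levels each is ``4**4 = 256`` runs — the comparison
    that motivates a 15-run optimal design.
    """
    if not levels_per_factor:
        raise ValueError("need at least one factor")
    if any(int(k) < 1 for k in levels_per_factor):
        raise ValueError("level counts must be >= 1")
    out = 1
    for k in levels_per_factor:
        out *= int(k)
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_STAT_COLUMNS = (
    "Std. dev.", "Mean", "C.V. %", "R2", "Adjusted R2", "Predicted R2",
    "Adequate precision",
)


def report(
    models: Mapping[str, FittedModel],
    stats: Mapping[str, FitStats],
    out_dir: str | Path,
    traces: Mapping[str, SelectionTrace] | None = None,
    optimization: OptimizationResult | None = None,
) -> dict[str, Path]:
    """Write equation, statistics, adequacy and candidate files.

    Deterministic: identical inputs give byte-identical files.  Returns the
    paths written, keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    eq_lines = []
    for name in sorted(models):
        m = models[name]
        eq_lines.append(
            f"{name}\t{m.transform.label()}\t{m.equation(decimals=2)}"
        )
    eq_path = out / "equations.tsv"
    eq_path.write_text(
        "response\ttransform\tequation\n" + "\n".join(eq_lines) + "\n"
    )
    written["equations"] = eq_path

    stat_lines = ["response\t" + "\t".join(_STAT_COLUMNS)]
    for name in sorted(stats):
        s = stats[name]
        vals = (
            s.std_dev, s.mean, s.cv_pct, s.r2, s.adj_r2, s.pred_r2,
            s.adequate_precision,
        )
        stat_lines.append(name + "\t" + "\t".join(f"{v:.4f}" for v in vals))
    st_path = out / "statistics.tsv"
    st_path.write_text("\n".join(stat_lines) + "\n")
    written["statistics"] = st_path

    adq_lines = ["response\tr2_gap_ok\tadequate_precision_ok\tpassed"]
    for name in sorted(stats):
        f = stats[name].adequacy()
        adq_lines.append(
            f"{name}\t{f.r2_gap_ok}\t{f.adequate_precision_ok}\t{f.passed}"
        )
    adq_path = out / "adequacy.tsv"
    adq_path.write_text("\n".join(adq_lines) + "\n")
    written["adequacy"] = adq_path

    if traces:
        for name in sorted(traces):
            p = out / f"selection_{name}.csv"
            traces[name].as_frame().to_csv(p, index=False, float_format="%.6f")
            written[f"selection_{name}"] = p
    if optimization is not None:
        p = out / "candidates.csv"
        optimization.as_frame().to_csv(p, index=False, float_format="%.6f")
        written["candidates"] = p
    return written


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable settings for a full pipeline run.

    Round-trips through YAML unchanged, and every stage's randomness is
    derived from the single ``seed`` so runs are reproducible from the
    config alone.
    """

    seed: int = 0
    design_path: str = ""
    responses_path: str = ""
    output_dir: str = "lipidmix_out"
    bounds: dict | None = None        # {names: [...], lower: [...], upper: [...]}
    selection_direction: str = "both"
    alpha: float = 0.05               # descriptive prescreen level
    goals: list[dict] = field(default_factory=list)
    fixed: dict[str, float] = field(default_factory=dict)
    n_starts: int = 50

    def component_bounds(self) -> ComponentBounds | None:
        if not self.bounds:
            return None
        return ComponentBounds(
            tuple(self.bounds["names"]),
            tuple(self.bounds["lower"]),
            tuple(self.bounds["upper"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
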