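"""Predicted-vs-experimental comparison: quadratic fits and endpoint reports.

The study summarizes model quality by regressing predicted values on
experimental ones, pooled across the five oven settings, with one quadratic
per formulation and target (crust temperature or weight loss), reporting the
coefficient of determination of each fit.  This module reproduces those
fits, the percent-increase summaries, and a tabulated comparison between a
simulated sweep and the published 40-min endpoints.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .properties import DomainError

__all__ = [
    "ValidationFit",
    "fit_quadratic",
    "percent_increase",
    "endpoint_report",
    "load_reference_endpoints",
]


@dataclass(frozen=True)
class ValidationFit:
    """Quadratic regression ``predicted = a2 x^2 + a1 x + a0`` on experimental x."""

    a2: float
    a1: float
    a0: float
    r_squared: float
    n: int
    target: str = ""             # "crust_T" | "weight_loss"
    formulation: str = ""        # "control" | "guar"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DomainError("a quadratic fit needs at least 3 points")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a2 * x**2 + self.a1 * x + self.a0

    def to_dict(self) -> dict:
        return asdict(self)


def fit_quadratic(
    experimental,
    predicted,
    target: str = "",
    formulation: str = "",
) -> ValidationFit:
    """Least-squares quadratic of predicted against experimental values.

    ``R^2 = 1 - SSres/SStot`` about the mean of the predicted series; a
    constant predicted series is reported with ``R^2 = 0``.  Points must be
    paired (same oven temperature and sampling time).
    """
    x = np.asarray(experimental, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("experimental and predicted series must be equal-length 1D")
    if x.size < 3:
        raise DomainError("a quadratic fit needs at least 3 points")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)
    a0, a1, a2 = coeffs
    resid = y - (a2 * x**2 + a1 * x + a0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ValidationFit(
        a2=float(a2), a1=float(a1), a0=float(a0),
        r_squared=r2, n=int(x.size), target=target, formulation=formulation,
    )


def percent_increase(low: float, high: float) -> float:
    """Relative increase from ``low`` to ``high`` in percent, ``100 (high-low)/low``."""
    if low <= 0:
        raise DomainError("percent increase needs a strictly positive base value")
    return 100.0 * (high - low) / low


def load_reference_endpoints() -> pd.DataFrame:
    """Published 40-min endpoints (crust temperature and weight loss).

    One row per formulation and oven temperature: the values reported for
    the end of the 40-min bake across the 190-230 C sweep.
    """
    ref = resources.files("toastbake").joinpath("data/reference_endpoints.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def endpoint_report(
    results: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    tolerance: float = 0.15,
) -> pd.DataFrame:
    """Model-vs-published comparison of 40-min endpoints.

    ``results`` is a sweep table (see ``run_grid``) with columns
    ``formulation``, ``T_oven_C``, ``crust_T_C``, ``weight_loss_pct``;
    ``reference`` defaults to the packaged endpoint table.  One row per
    (formulation, oven temperature) pair, with per-endpoint relative errors
    for crust temperature and weight loss; keys present in only one table
    produce explicit gap rows rather than being dropped.  Relative errors
    outside ``tolerance`` are flagged.
    """
    if reference is None:
        reference = load_reference_endpoints()
    keys = ["formulation", "T_oven_C"]
    merged = pd.merge(
        results, reference, on=keys, how="outer",
        suffixes=("_model", "_ref"), indicator=True,
    ).sort_values(keys, kind="stable").reset_index(drop=True)

    rows = []
    for _, row in merged.iterrows():
        base = {k: row[k] for k in keys}
        if row["_merge"] != "both":
            side = "results" if row["_merge"] == "left_only" else "reference"
            rows.append({**base,
                         "crust_T_C_model": np.nan, "crust_T_C_ref": np.nan,
                         "crust_T_rel_error": np.nan,
                         "weight_loss_model": np.nan, "weight_loss_ref": np.nan,
                         "weight_loss_rel_error": np.nan,
                         "within_tol": False, "note": f"present only in {side}"})
            continue
        out = dict(base)
        flags = []
        for target, label in (("crust_T_C", "crust_T"), ("weight_loss_pct", "weight_loss")):
            model, ref_v = row[f"{target}_model"], row[f"{target}_ref"]
            rel = (model - ref_v) / ref_v if ref_v != 0 else np.nan
            out[f"{label if label != 'crust_T' else 'crust_T_C'}_model"] = model
            out[f"{label if label != 'crust_T' else 'crust_T_C'}_ref"] = ref_v
            out[f"{label}_rel_error"] = rel
            flags.append(abs(rel) <= tolerance)
        out["within_tol"] = bool(all(flags))
        out["note"] = ""
        rows.append(out)
    return pd.DataFrame(rows)
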