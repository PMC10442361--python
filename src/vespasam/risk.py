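"""Administrative-unit aggregation, report standardization, validation
against abundance, and hazard x sensitivity risk indices.

Risk for a unit is defined as hazard (the unit's predicted hornet
abundance, on the log(x+1) scale used for mapping) multiplied by a
sensitivity factor: residential population for the human-health index,
honeybee-colony count for the honeybee-loss index. Each index is classed
into five quantile levels for mapping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from .evaluation import CorrelationTestResult, correlation_test
from .raster import RasterGrid

__all__ = [
    "aggregate_admin",
    "standardize_reports",
    "validate_abundance",
    "risk_index",
    "classify_levels",
    "build_unit_risk_table",
]


def aggregate_admin(prediction: RasterGrid, polygons) -> pd.DataFrame:
    """Per-unit mean of log(x+1)-transformed predictions.

    A cell belongs to the unit whose polygon contains its centre. Units
    containing no cell centre get NaN and are flagged missing.
    """
    xmesh, ymesh = prediction.center_mesh()
    xs, ys = xmesh.ravel(), ymesh.ravel()
    logvals = np.log1p(prediction.values.ravel().astype(float))
    rows = []
    for i, poly in enumerate(polygons):
        inside = shapely.contains_xy(poly, xs, ys)
        if inside.any():
            rows.append({"unit_id": i, "mean_log_abundance": float(logvals[inside].mean()),
                         "n_cells": int(inside.sum()), "missing": False})
        else:
            rows.append({"unit_id": i, "mean_log_abundance": np.nan,
                         "n_cells": 0, "missing": True})
    return pd.DataFrame(rows)


def standardize_reports(report_count, population):
    """Nest-removal reports per capita: report_count / population.

    Units with zero population get NaN (excluded downstream) with a
    warning rather than an error.
    """
    report_count = np.asarray(report_count, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(report_count < 0) or np.any(population < 0):
        raise ValueError("counts and populations must be nonnegative")
    out = np.full(np.broadcast(report_count, population).shape, np.nan)
    report_b = np.broadcast_to(report_count, out.shape)
    pop_b = np.broadcast_to(population, out.shape)
    ok = pop_b > 0
    if not ok.all():
        warnings.warn("zero-population units excluded from per-capita rates", stacklevel=2)
    out[ok] = report_b[ok] / pop_b[ok]
    if np.isscalar(population) and np.ndim(out) == 0:
        return float(out)
    return out


def validate_abundance(
    units: pd.DataFrame,
    abundance_col: str = "mean_log_abundance",
    reports_col: str = "reports_per_capita",
    apiary_col: str = "apiary_rate",
) -> dict[str, CorrelationTestResult]:
    """Correlation tests of aggregated abundance against the two external
    signals: standardized nest-removal reports and apiary appearance rate.

    Rows with missing values in a pair are dropped for that pair.
    """
    results = {}
    for name, col in (("reports", reports_col), ("apiary", apiary_col)):
        if col not in units.columns:
            continue
        sub = units[[abundance_col, col]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >= 3 complete units for the {name} correlation")
        results[name] = correlation_test(
            sub[abundance_col].to_numpy(), sub[col].to_numpy()
        )
    return results


def risk_index(hazard, sensitivity):
    """Risk = hazard x sensitivity (bilinear, zero-absorbing)."""
    hazard = np.asarray(hazard, dtype=float)
    sensitivity = np.asarray(sensitivity, dtype=float)
    if np.any(hazard < 0) or np.any(sensitivity < 0):
        raise ValueError("hazard and sensitivity must be nonnegative")
    out = hazard * sensitivity
    if out.ndim == 0:
        return float(out)
    return out


def classify_levels(values, n_classes: int = 5) -> np.ndarray:
    """Quantile classes 1..n_classes (1 = lowest fifth for the default 5).

    Breaks sit at the 20/40/60/80th percentiles; classification is
    monotone (a larger value never gets a smaller class). With fewer
    distinct values than classes the classing degrades gracefully (ties
    share a class) with a warning. NaNs propagate as 0 (unclassed).
    """
    values = np.asarray(values, dtype=float)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite values to classify")
    if np.unique(finite).size < n_classes:
        warnings.warn(
            "fewer distinct values than classes: coarser classing", stacklevel=2
        )
    qs = np.percentile(finite, np.linspace(0, 100, n_classes + 1)[1:-1])
    out = np.zeros(values.shape, dtype=int)
    ok = np.isfinite(values)
    out[ok] = 1 + np.sum(values[ok][:, None] > qs[None, :], axis=1)
    return out


def build_unit_risk_table(
    units,
    prediction: RasterGrid,
    n_classes: int = 5,
) -> pd.DataFrame:
    """Full per-unit risk table from admin units and a prediction raster.

    Combines zonal log-abundance aggregation (hazard), per-capita report
    standardization, both hazard x sensitivity indices and their
    five-level quantile classes.
    """
    agg = aggregate_admin(prediction, [u.polygon for u in units])
    df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "population": [u.population for u in units],
            "colonies": [u.colonies for u in units],
            "report_count": [u.report_count for u in units],
            "apiary_rate": [getattr(u, "apiary_rate", np.nan) for u in units],
        }
    ).merge(agg, on="unit_id")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["reports_per_capita"] = standardize_reports(
            df["report_count"].to_numpy(), df["population"].to_numpy()
        )
    hazard = df["mean_log_abundance"].to_numpy()
    df["risk_health"] = np.where(
        np.isfinite(hazard), risk_index(np.nan_to_num(hazard), df["population"]), np.nan
    )
    df["risk_honeybee"] = np.where(
        np.isfinite(hazard), risk_index(np.nan_to_num(hazard), df["colonies"]), np.nan
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["risk_health_class"] = classify_levels(df["risk_health"].to_numpy(), n_classes)
        df["risk_honeybee_class"] = classify_levels(df["risk_honeybee"].to_numpy(), n_classes)
    return df
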