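"""Covariate engineering: foraging-buffer land composition, alignment of
fine-resolution products to the coarse climate grid, and the pairwise
Pearson collinearity filter.

Workers of the hornet forage mostly within ~1 km of the nest, so the
land-type covariates are the areas (km^2) of each land-cover class inside a
1 km-radius disc around a location. A fine cell contributes to the disc iff
its *centre* lies within the radius of the query point; the class area is
then (number of contributing cells of that class) x (fine-cell area).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .raster import GridMismatchError, RasterGrid

__all__ = [
    "land_composition_buffer",
    "align_to_coarse",
    "collinearity_filter",
    "CollinearityFilter",
    "site_mean_abundance",
    "build_covariate_table",
]


def land_composition_buffer(
    landcover: RasterGrid,
    centers,
    radius: float = 1.0,
    n_classes: int | None = None,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-centre area (km^2) of each land-cover class within ``radius``.

    Parameters
    ----------
    landcover : fine raster of integer class codes (0-based).
    centers : sequence of (x, y) points in the raster's coordinate system.
    radius : buffer radius in km (default 1, the foraging range).

    Returns
    -------
    DataFrame with one row per centre: one area column per class, plus
    ``partial_coverage`` (True when the disc extends beyond the raster, in
    which case only covered cells are counted) and ``outside`` (True when
    the centre itself falls outside the raster extent; its areas are NaN).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if n_classes is None:
        finite = landcover.values[np.isfinite(landcover.values.astype(float))]
        n_classes = int(finite.max()) + 1 if finite.size else 1
    if class_names is None:
        class_names = [f"class_{k}" for k in range(n_classes)]
    if len(class_names) != n_classes:
        raise ValueError("class_names length must equal n_classes")

    f = landcover.cell
    cell_area = f * f
    xmin, ymin, xmax, ymax = landcover.extent
    nrows, ncols = landcover.values.shape
    labels = landcover.values

    areas = np.full((len(centers), n_classes), np.nan)
    partial = np.zeros(len(centers), dtype=bool)
    outside = np.zeros(len(centers), dtype=bool)

    for i, (cx, cy) in enumerate(centers):
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            outside[i] = True
            continue
        # candidate fine-cell index window around the disc
        c0 = int(np.floor((cx - radius - xmin) / f))
        c1 = int(np.ceil((cx + radius - xmin) / f))
        r0 = int(np.floor((ymax - (cy + radius)) / f))
        r1 = int(np.ceil((ymax - (cy - radius)) / f))
        if c0 < 0 or r0 < 0 or c1 > ncols or r1 > nrows:
            partial[i] = True
        c0c, c1c = max(c0, 0), min(c1, ncols)
        r0c, r1c = max(r0, 0), min(r1, nrows)
        cols = np.arange(c0c, c1c)
        rows = np.arange(r0c, r1c)
        xc = xmin + (cols + 0.5) * f
        yc = ymax - (rows + 0.5) * f
        dx2 = (xc - cx) ** 2
        dy2 = (yc - cy) ** 2
        mask = dy2[:, None] + dx2[None, :] <= radius**2
        win = labels[r0c:r1c, c0c:c1c]
        counts = np.bincount(win[mask].astype(int), minlength=n_classes)
        areas[i] = counts[:n_classes] * cell_area

    df = pd.DataFrame(areas, columns=class_names)
    df["partial_coverage"] = partial
    df["outside"] = outside
    return df


def align_to_coarse(
    landcover: RasterGrid,
    coarse: RasterGrid,
    radius: float = 1.0,
    n_classes: int | None = None,
    class_names: list[str] | None = None,
) -> dict[str, RasterGrid]:
    """Buffer composition evaluated at every coarse-cell centre.

    Returns one coarse raster per class, bitwise-aligned with ``coarse``
    (the climate grid). Equivalent to :func:`land_composition_buffer` at
    the list of coarse-cell centres, reshaped.
    """
    tol = 1e-9
    if (
        abs(landcover.xll - coarse.xll) > tol
        or abs(landcover.yll - coarse.yll) > tol
        or abs(landcover.ncols * landcover.cell - coarse.ncols * coarse.cell) > tol
        or abs(landcover.nrows * landcover.cell - coarse.nrows * coarse.cell) > tol
    ):
        raise GridMismatchError("land-cover raster does not cover the coarse grid extent")
    xmesh, ymesh = coarse.center_mesh()
    centers = np.column_stack([xmesh.ravel(), ymesh.ravel()])
    comp = land_composition_buffer(
        landcover, centers, radius=radius, n_classes=n_classes, class_names=class_names
    )
    out = {}
    for name in comp.columns:
        if name in ("partial_coverage", "outside"):
            continue
        out[name] = coarse.copy_with(
            comp[name].to_numpy(dtype=float).reshape(coarse.values.shape)
        )
    return out


# --------------------------------------------------------------------------
# Collinearity filter
# --------------------------------------------------------------------------


class CollinearityFilter(TransformerMixin, BaseEstimator):
    """Greedy priority-ordered Pearson collinearity filter.

    Variables are visited in ``priority`` order (default: column order); a
    variable is retained iff its absolute Pearson correlation with every
    already-retained variable is <= ``threshold``. After fitting, no
    retained pair exceeds the threshold, and within any violating pair the
    higher-priority variable is the one kept. Constant columns (undefined
    correlation) are treated as uncorrelated, with a warning.

    Attributes
    ----------
    retained_ : list of retained column names
    dropped_ : dict dropped name -> retained name that excluded it
    """

    def __init__(self, threshold: float = 0.8, priority: list[str] | None = None):
        self.threshold = threshold
        self.priority = priority

    def fit(self, X: pd.DataFrame, y=None) -> "CollinearityFilter":
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 variables")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 rows")
        order = list(self.priority) if self.priority is not None else list(X.columns)
        missing = [c for c in X.columns if c not in order]
        if missing:
            raise ValueError(f"priority does not cover variables: {missing}")
        order = [c for c in order if c in X.columns]

        constant = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
        if constant:
            warnings.warn(
                f"constant columns treated as uncorrelated: {constant}", stacklevel=2
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = X.astype(float).corr().abs().fillna(0.0)

        retained: list[str] = []
        dropped: dict[str, str] = {}
        for name in order:
            blocker = next(
                (r for r in retained if corr.loc[name, r] > self.threshold), None
            )
            if blocker is None:
                retained.append(name)
            else:
                dropped[name] = blocker
        self.retained_ = retained
        self.dropped_ = dropped
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "retained_"):
            raise AttributeError("CollinearityFilter is not fitted")
        return pd.DataFrame(X)[self.retained_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.retained_, dtype=object)


def collinearity_filter(
    table: pd.DataFrame, threshold: float = 0.8, priority: list[str] | None = None
) -> list[str]:
    """Retained variable names after the priority-ordered Pearson filter."""
    return CollinearityFilter(threshold=threshold, priority=priority).fit(table).retained_


# --------------------------------------------------------------------------
# Site table
# --------------------------------------------------------------------------


def site_mean_abundance(records) -> pd.DataFrame:
    """One row per site with the multi-year mean trap catch.

    The response of the abundance models is this mean (or its log(x+1)
    transform); sites surveyed a single year keep that year's count.
    """
    rows = []
    for rec in records:
        if not rec.counts_by_year:
            raise ValueError(f"site {rec.site_id} has no yearly counts")
        rows.append(
            {
                "site_id": rec.site_id,
                "x": rec.x,
                "y": rec.y,
                "n_years": len(rec.counts_by_year),
                "mean_count": float(np.mean(list(rec.counts_by_year.values()))),
            }
        )
    return pd.DataFrame(rows)


def build_covariate_table(
    sites: pd.DataFrame,
    climate: dict[str, RasterGrid],
    land_composition: dict[str, RasterGrid],
) -> pd.DataFrame:
    """Covariate table for model fitting: one row per site, one column per
    climate variable (native units) and per land-class buffer area (km^2),
    sampled at the coarse cell containing the site."""
    out = sites[["site_id", "x", "y"]].copy()
    xs = sites["x"].to_numpy(dtype=float)
    ys = sites["y"].to_numpy(dtype=float)
    for name, grid in {**climate, **land_composition}.items():
        out[name] = grid.sample(xs, ys)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    return out
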