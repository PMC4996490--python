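"""Prediction maps: relative intensity, decile classes, abundance scaling.

The fitted model is evaluated on a regular grid of 2 x 10-km cells with
offset 0 (one survey-year scale; only relative intensity matters).  Cells
are classified 1 (low use) to 10 (high use) by the percentiles of the
prediction distribution so every class covers the same area, with tied
values kept together.  Scaling the map so its cells sum to an external
population total converts relative intensity into expected eagle numbers
per cell, and region totals follow by summing cells whose centre points
fall inside a region polygon.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from .fit import ModelFit


def predict_grid(fit: ModelFit, grid_cov: pd.DataFrame) -> pd.DataFrame:
    """Relative intensity exp(X beta-hat) per grid cell (offset 0)."""
    missing = [c for c in fit.exog_names
               if c != "const" and not c.startswith("aspect:") and not c.endswith("^2")
               and c not in grid_cov.columns]
    if missing:
        raise KeyError(f"grid covariates missing model terms: {missing}")
    from .covariates import build_design
    X = build_design(grid_cov, fit.spec) if fit.spec is not None else grid_cov
    bad = X[list(fit.exog_names)].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"missing covariate values in cells: {list(X.index[bad])[:10]}")
    out = grid_cov.copy()
    out["intensity"] = fit.predict(X)
    return out


def classify_deciles(values) -> np.ndarray:
    """Equal-area classes 1..10 from the prediction distribution.

    Brute-force stable sort assignment: position k of n gets class
    floor(10 k / n) + 1, then every run of exactly equal values is forced
    into the class of its first member, so class sizes differ only by
    tie-group sizes.  A constant map collapses to one class with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 10:
        raise ValueError("need at least 10 cells to form decile classes")
    order = np.argsort(v, kind="stable")
    base = np.floor(np.arange(n) * 10 / n).astype(int) + 1
    sv = v[order]
    cls_sorted = base.copy()
    run_start = 0
    for i in range(1, n + 1):
        if i == n or sv[i] != sv[run_start]:
            cls_sorted[run_start:i] = cls_sorted[run_start]
            run_start = i
    classes = np.empty(n, dtype=int)
    classes[order] = cls_sorted
    if np.unique(v).size == 1:
        warnings.warn("all prediction values identical; map collapses to one class",
                      stacklevel=2)
    return classes


def scale_to_abundance(grid: pd.DataFrame, total: float,
                       regions: dict | None = None,
                       intensity_col: str = "intensity"):
    """Scale relative intensity to expected eagle numbers per cell.

    ``expected = total * intensity / sum(intensity)``, so the map sums to
    ``total`` exactly.  ``regions`` maps names to shapely polygons; a
    region's estimate is the sum over cells whose (x, y) centres fall
    inside it (centre-in-polygon rule).  Returns ``(grid, region_totals)``.
    """
    if total <= 0:
        raise ValueError("population total must be > 0")
    out = grid.copy()
    w = out[intensity_col].to_numpy(dtype=float)
    s = w.sum()
    if s <= 0:
        raise ValueError("total predicted intensity is zero; cannot scale")
    out["expected_eagles"] = total * w / s
    region_totals = {}
    if regions:
        pts = shapely.points(out["x"].to_numpy(), out["y"].to_numpy())
        for name, poly in regions.items():
            inside = shapely.contains(poly, pts)
            if not inside.any():
                warnings.warn(f"region {name!r} contains no grid-cell centres",
                              stacklevel=2)
            region_totals[name] = float(out.loc[inside, "expected_eagles"].sum())
    return out, region_totals
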