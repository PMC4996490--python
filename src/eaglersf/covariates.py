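"""Unit-level covariate summaries, collinearity screening and model designs.

Each sampling unit is summarised from the landscape rasters: medians of
continuous fields over the cells whose centres fall in the unit rectangle,
class proportions for land-cover fields, centre-point values for
distance-to-road fields, and the modal quadrant for aspect.  Before
modelling, highly correlated covariate pairs (|Pearson r| above a
threshold, default 0.6) are flagged so only one member enters the model;
correlated candidates can be compared head-to-head by univariate AIC.
Model designs support quadratic terms tied to their linear parents and a
categorical aspect expanded to indicators with N as the reference level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ASPECT_LEVELS, Landscape


def summarize_units(units: pd.DataFrame, landscape: Landscape,
                    half_width_km: float = 1.0) -> pd.DataFrame:
    """Covariate summary table for sampling units.

    ``units`` must carry x_start, x_end, y (the transect line through the
    unit centre); the rectangle spans ``y +- half_width_km``.  Summaries per
    field kind: continuous -> median, proportion -> mean share,
    distance -> centre-point value, aspect -> modal quadrant letter.
    """
    recs = {}
    for name, spec in landscape.specs.items():
        vals = []
        for u in units.itertuples():
            cells = landscape.cells_in_rect(name, u.x_start, u.x_end,
                                            u.y - half_width_km, u.y + half_width_km)
            if cells.size == 0:
                raise ValueError(
                    f"no raster cells of field {name!r} intersect unit {u.Index!r}")
            if spec.kind == "continuous":
                vals.append(float(np.median(cells)))
            elif spec.kind == "proportion":
                vals.append(float(cells.mean()))
            elif spec.kind == "distance":
                xc = (u.x_start + u.x_end) / 2.0
                vals.append(landscape.value_at(name, xc, u.y))
            elif spec.kind == "aspect":
                codes, counts = np.unique(cells.astype(int), return_counts=True)
                vals.append(ASPECT_LEVELS[int(codes[np.argmax(counts)])])
            else:  # pragma: no cover - specs validated at generation
                raise ValueError(f"unknown covariate kind {spec.kind!r}")
        recs[name] = vals
    return pd.DataFrame(recs, index=units.index)


def screen_correlation(cov: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Flag continuous covariate pairs with |Pearson r| above the threshold.

    Zero-variance columns are excluded with a warning.  Returns a frame
    with columns a, b, r (symmetric: each unordered pair listed once).
    """
    num = cov.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 units to screen correlations")
    keep = []
    for c in num.columns:
        if num[c].std(ddof=0) == 0:
            warnings.warn(f"covariate {c!r} has zero variance; excluded from screening",
                          stacklevel=2)
        else:
            keep.append(c)
    rows = []
    corr = num[keep].corr()
    for a, b in itertools.combinations(keep, 2):
        r = corr.loc[a, b]
        if abs(r) > threshold:
            rows.append({"a": a, "b": b, "r": r})
    return pd.DataFrame(rows, columns=["a", "b", "r"])


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list for an RSF design.

    Terms are covariate names; ``"name^2"`` adds the quadratic (its linear
    parent must also be listed); ``"aspect"`` expands to S/E/W indicators
    with N as the reference.  The intercept is implicit.
    """

    terms: tuple

    def __init__(self, terms):
        object.__setattr__(self, "terms", tuple(terms))
        for t in self.terms:
            if t.endswith("^2") and t[:-2] not in self.terms:
                raise ValueError(
                    f"quadratic term {t!r} requires its linear parent {t[:-2]!r} in the spec")

    def without(self, term: str) -> "ModelSpec":
        return ModelSpec(tuple(t for t in self.terms if t != term))

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)


def build_design(cov: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix (with leading ``const`` column) for a model spec."""
    cols = {"const": np.ones(len(cov))}
    for t in spec:
        if t == "aspect":
            for lev in ASPECT_LEVELS[1:]:
                cols[f"aspect:{lev}"] = (cov["aspect"] == lev).astype(float).to_numpy()
        elif t.endswith("^2"):
            base = t[:-2]
            if base not in cov.columns:
                raise KeyError(f"covariate {base!r} not in table")
            cols[t] = cov[base].to_numpy(dtype=float) ** 2
        else:
            if t not in cov.columns:
                raise KeyError(f"covariate {t!r} not in table")
            cols[t] = cov[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cov.index)


def compare_univariate(cov: pd.DataFrame, candidate_a: str, candidate_b: str,
                       pseudocounts, offset):
    """AIC comparison of two single-covariate NB models with offset.

    Used to adjudicate between correlated candidates (only one may enter
    the full model).  Returns ``(preferred, aic_a, aic_b)``; ``preferred``
    is None on a numerical tie.
    """
    from .fit import fit_nb

    fits = {}
    for name in (candidate_a, candidate_b):
        X = build_design(cov, ModelSpec((name,)))
        fits[name] = fit_nb(X, pseudocounts, offset=offset)
    aic_a, aic_b = fits[candidate_a].aic, fits[candidate_b].aic
    if abs(aic_a - aic_b) < 1e-6:
        return None, aic_a, aic_b
    return (candidate_a if aic_a < aic_b else candidate_b), aic_a, aic_b


def full_model_spec(drop=("slope", "ndvi", "water")) -> ModelSpec:
    """The study-style full model: all covariates minus the screened-out set.

    Defaults drop slope (correlated with ruggedness and forest), NDVI
    (correlated with forest, which wins the univariate AIC comparison) and
    the water/ice/snow proportion (a rare class).  Quadratics on elevation,
    slope, NDVI and solar enter when their parents survive screening.
    """
    continuous = ["elevation", "slope", "ndvi", "solar", "popden", "ruggedness",
                  "wind", "road1_dist", "road2_dist"]
    quad_parents = ["elevation", "slope", "ndvi", "solar"]
    landcover = ["shrub", "grassland", "crop", "developed", "forest", "barren",
                 "wetland", "water"]
    terms = []
    for c in continuous:
        if c in drop:
            continue
        terms.append(c)
        if c in quad_parents:
            terms.append(f"{c}^2")
    terms.append("aspect")
    terms.extend(c for c in landcover if c not in drop)
    return ModelSpec(terms)


def final_model_spec() -> ModelSpec:
    """The study's final seven-term model (plus intercept)."""
    return ModelSpec(("elevation", "elevation^2", "solar", "solar^2",
                      "forest", "developed", "wind"))
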