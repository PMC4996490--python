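"""Bootstrap confidence intervals and marginal-effect summaries.

Inference respects the survey design: whole transects are resampled with
replacement (the transect is the independent sampling unit), every unit
instance on a selected transect enters with the transect's multiplicity,
and each iteration redraws one detection probability per stratum from a
truncated normal around its published mean and SE — propagating detection
uncertainty into the pseudocounts.  The fixed final model is refitted per
iteration (structure is not reselected) and the central 90% of each
coefficient's bootstrap distribution is the confidence interval
(percentile method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import ModelSpec, build_design
from .detection import DetectionTable, round_half_away, stratum_group_matrix
from .fit import ModelFit, fit_nb


@dataclass
class BootstrapResult:
    draws: pd.DataFrame          # converged iterations x coefficients
    ci90: pd.DataFrame           # index = coefficients, columns lower/upper
    n_iterations: int
    failures: int


def bootstrap_cis(obs_units: pd.DataFrame, units: pd.DataFrame, cov: pd.DataFrame,
                  spec: ModelSpec, detection: DetectionTable,
                  transect_ids=None, n_iter: int = 1000, seed: int = 0,
                  point_fit: ModelFit | None = None, p_floor: float = 0.01,
                  max_failure_frac: float = 0.20) -> BootstrapResult:
    """Transect bootstrap with detection-probability resampling.

    Parameters
    ----------
    obs_units : observation rows already assigned to units
        (columns unit_id, group_size, obs_type, side)
    units : frame indexed by unit_id with transect_id and n_years
    cov : unit covariate table aligned with ``units``
    spec : the fixed final model specification
    detection : stratum probabilities with SEs
    transect_ids : full primary transect list to resample from
        (defaults to the transects represented among ``units``)
    n_iter, seed : bootstrap size and RNG seed
    point_fit : optional fit on the original data, used as a warm start

    Iterations whose refit fails are logged and skipped; more than
    ``max_failure_frac`` failures aborts.
    """
    rng = np.random.default_rng(seed)
    if transect_ids is None:
        transect_ids = np.asarray(sorted(units["transect_id"].unique()))
    else:
        transect_ids = np.asarray(transect_ids)
    X_all = build_design(cov, spec)
    G = stratum_group_matrix(obs_units, units.index, detection).to_numpy()
    n_years = units["n_years"].to_numpy(dtype=float)
    units_by_transect = {
        t: np.flatnonzero(units["transect_id"].to_numpy() == t) for t in transect_ids
    }
    start = None if point_fit is None else point_fit.params.to_numpy()
    start_theta = 1.0 if point_fit is None else point_fit.theta

    draws = []
    failures = 0
    for _ in range(n_iter):
        chosen = rng.choice(transect_ids, size=len(transect_ids), replace=True)
        idx = np.concatenate([units_by_transect[t] for t in chosen]) if len(chosen) else np.array([], int)
        if idx.size == 0:
            failures += 1
            continue
        p_draw = detection.prob_vector(rng=rng, floor=p_floor).to_numpy()
        raw = G[idx] @ (1.0 / p_draw)
        y = round_half_away(raw).astype(int)
        try:
            fit = fit_nb(X_all.iloc[idx], y, offset=np.log(n_years[idx]),
                         start_params=start, start_theta=start_theta)
            draws.append(fit.params)
        except Exception:
            failures += 1
    if failures > max_failure_frac * n_iter:
        raise RuntimeError(
            f"bootstrap failure rate too high: {failures}/{n_iter} iterations failed")
    if failures:
        warnings.warn(f"{failures} bootstrap iteration(s) failed and were skipped",
                      stacklevel=2)
    draws_df = pd.DataFrame(draws).reset_index(drop=True)
    lo = draws_df.quantile(0.05)
    hi = draws_df.quantile(0.95)
    ci = pd.DataFrame({"lower": lo, "upper": hi})
    return BootstrapResult(draws=draws_df, ci90=ci, n_iterations=n_iter,
                           failures=failures)


def marginal_curve(fit: ModelFit, cov: pd.DataFrame, name: str,
                   grid=None, n_grid: int = 50) -> pd.DataFrame:
    """Marginal effect of one covariate, scaled to a maximum of 1.

    All other covariates are held at their medians (modal level for
    aspect); the covariate's quadratic term, if in the model, follows the
    grid.  Returns a frame with the grid and the scaled relative intensity
    (offset 0, i.e. per survey-year, though scaling cancels it).
    """
    if name not in fit.params.index:
        raise KeyError(f"covariate {name!r} is not a term of the fitted model")
    if grid is None:
        grid = np.linspace(cov[name].min(), cov[name].max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    ref = {}
    for col in fit.exog_names:
        if col == "const":
            ref[col] = 1.0
        elif col.startswith("aspect:"):
            lev = col.split(":", 1)[1]
            ref[col] = float((cov["aspect"].mode().iloc[0]) == lev)
        elif col.endswith("^2"):
            ref[col] = float(np.median(cov[col[:-2]]) ** 2)
        else:
            ref[col] = float(np.median(cov[col]))
    X = pd.DataFrame([ref] * len(grid))
    X[name] = grid
    if f"{name}^2" in fit.exog_names:
        X[f"{name}^2"] = grid ** 2
    resp = fit.predict(X)
    return pd.DataFrame({name: grid, "relative_use": resp / resp.max()})


def quadratic_vertex(beta_linear: float, beta_quadratic: float):
    """Turning point of a fitted quadratic response, -b1/(2 b2).

    Returns ``(vertex, kind)`` with kind 'maximum' iff the quadratic
    coefficient is negative (else 'minimum').
    """
    if beta_quadratic == 0:
        raise ValueError("no vertex: quadratic coefficient is zero")
    vertex = -beta_linear / (2.0 * beta_quadratic)
    return vertex, ("maximum" if beta_quadratic < 0 else "minimum")
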