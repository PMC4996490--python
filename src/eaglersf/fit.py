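"""Offset negative-binomial RSF fitting, BIC selection and diagnostics.

The response is the rounded, detection-adjusted pseudocount per sampling
unit; the linear predictor carries a fixed offset ln(effort-years) so
coefficients are standardised to one survey-year:

    ln E[count_i] = ln(n_years_i) + b0 + b1 x_1i + ... + bp x_pi

Counts are NB2 (variance mu + mu^2/theta).  Maximum likelihood is obtained
by alternating an IRLS fit of the regression coefficients at fixed
dispersion with a one-dimensional profile-likelihood update of theta,
iterated to a 1e-8 log-likelihood tolerance.  Model selection is backwards
single-term removal under BIC with the structural rule that a linear term
cannot leave while its quadratic remains; the categorical aspect enters and
leaves as a block.  Diagnostics: residual-deviance goodness of fit against
chi-square, and Moran's I on deviance residuals with binary neighbour
weights inside a distance radius (default 200 km, flag at I > 0.20).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .covariates import ModelSpec, build_design

_THETA_LOG_BOUNDS = (-7.0, 16.0)  # theta in [~1e-3, ~9e6]; upper end ~ Poisson


@dataclass
class ModelFit:
    """A fitted offset-NB2 model.

    ``bic`` uses the fixed convention -2 ll + (p + 2) ln(n) where p + 1 is
    the number of regression coefficients (including the intercept) and the
    dispersion counts as one more parameter; n is the number of modelled
    units.  ``df_resid`` is n - (p + 1).
    """

    params: pd.Series
    bse: pd.Series
    theta: float
    llf: float
    aic: float
    bic: float
    mu: np.ndarray
    resid_deviance: np.ndarray
    df_resid: int
    nobs: int
    converged: bool
    exog_names: tuple
    spec: ModelSpec | None = None
    offset: np.ndarray | None = None
    n_iter: int = 0

    @property
    def deviance(self) -> float:
        return float(np.sum(self.resid_deviance ** 2))

    def predict(self, X: pd.DataFrame, offset=0.0) -> np.ndarray:
        """Expected count for new design rows (offset in log-years)."""
        Xm = X[list(self.exog_names)].to_numpy(dtype=float)
        return np.exp(Xm @ self.params.to_numpy() + np.asarray(offset))

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "theta": self.theta,
            "llf": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "df_resid": self.df_resid,
            "nobs": self.nobs,
            "converged": self.converged,
            "terms": list(self.spec.terms) if self.spec is not None else None,
        }


def _nb2_loglik(y, mu, theta):
    """Exact NB2 log likelihood (theta -> inf limit handled as Poisson)."""
    if math.isinf(theta):
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    ))


def _profile_theta(y, mu, theta0):
    """Profile-ML update of the dispersion at fixed fitted means."""
    def neg(t_log):
        return -_nb2_loglik(y, mu, math.exp(t_log))

    res = optimize.minimize_scalar(neg, bounds=_THETA_LOG_BOUNDS, method="bounded",
                                   options={"xatol": 1e-10})
    return math.exp(res.x)


def _nb2_deviance_resid(y, mu, theta):
    """Signed square roots of the unit NB2 deviances."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = (y + theta) * np.log((y + theta) / (mu + theta))
    d = 2.0 * (term1 - term2)
    d = np.clip(d, 0.0, None)  # guard tiny negatives from roundoff
    return np.sign(y - mu) * np.sqrt(d)


def fit_nb(X: pd.DataFrame, y, offset=None, start_params=None, start_theta=1.0,
           tol: float = 1e-8, max_iter: int = 200) -> ModelFit:
    """Maximum-likelihood offset-NB2 fit.

    Parameters
    ----------
    X : design matrix including the ``const`` column
    y : non-negative integer pseudocounts
    offset : log effort (ln n_years) per unit, default 0
    start_params, start_theta : warm starts (used heavily by the bootstrap)

    Raises on an all-zero response (degenerate: no information about
    habitat contrasts) and on non-convergence.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    n, p1 = X.shape
    if n <= p1 + 1:
        raise ValueError(f"need n > p + 2 observations (n={n}, columns={p1})")
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError("pseudocounts must be non-negative integers")
    if not np.any(yv > 0):
        raise ValueError("all pseudocounts are zero; NB fit undefined "
                         "(consider a degenerate Poisson/zero model)")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(off)):
        raise ValueError("offsets must be finite")

    theta = float(start_theta)
    beta = None if start_params is None else np.asarray(start_params, dtype=float)
    ll_prev = -np.inf
    glm_res = None
    converged = False
    for it in range(1, max_iter + 1):
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm_res = sm.GLM(yv, X, family=fam, offset=off).fit(
                start_params=beta, maxiter=100)
        beta = glm_res.params.to_numpy()
        mu = np.asarray(glm_res.mu)
        theta = _profile_theta(yv, mu, theta)
        ll = _nb2_loglik(yv, mu, theta)
        # alternating ML is monotone, so lack of improvement means converged
        # (guards against likelihood jitter on a flat dispersion profile)
        delta = ll - ll_prev
        if delta < tol:
            converged = True
            break
        ll_prev = ll
    if not converged:
        raise RuntimeError(
            f"NB2 fit did not converge in {max_iter} alternations "
            f"(last log-likelihood change {delta:.3g})")

    k = p1 + 1  # regression coefficients + dispersion
    resid = _nb2_deviance_resid(yv, mu, theta)
    return ModelFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(np.asarray(glm_res.bse), index=X.columns),
        theta=theta,
        llf=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * math.log(n),
        mu=mu,
        resid_deviance=resid,
        df_resid=n - p1,
        nobs=n,
        converged=True,
        exog_names=tuple(X.columns),
        offset=off,
        n_iter=it,
    )


def fit_spec(cov: pd.DataFrame, y, offset, spec: ModelSpec, **kw) -> ModelFit:
    """Fit a model spec against a covariate table."""
    fit = fit_nb(build_design(cov, spec), y, offset=offset, **kw)
    fit.spec = spec
    return fit


def _removable_terms(spec: ModelSpec):
    """Terms eligible for deletion: a linear term is locked while its
    quadratic remains; aspect leaves as a block; quadratics always eligible."""
    out = []
    for t in spec:
        if not t.endswith("^2") and f"{t}^2" in spec.terms:
            continue
        out.append(t)
    return out


def backwards_bic(cov: pd.DataFrame, y, offset, full_spec: ModelSpec,
                  tie_tol: float = 1e-6):
    """Backwards single-term removal under BIC from the full model.

    At each step the deletion that lowers BIC the most is applied; ties
    within ``tie_tol`` are broken by removing the term with the smallest
    |coefficient/SE| (deterministic traces).  Stops when no deletion
    lowers BIC.  Returns ``(final_fit, trace)`` where the trace records
    per step the BIC of every candidate deletion, the term removed, and
    the maximum relative change in surviving coefficients (the
    multicollinearity stability monitor).
    """
    current = fit_spec(cov, y, offset, full_spec)
    trace = [{"step": 0, "removed": None, "bic": current.bic,
              "n_terms": len(full_spec), "max_rel_coef_change": np.nan}]
    step = 0
    while True:
        step += 1
        candidates = []
        for t in _removable_terms(current.spec):
            try:
                cand = fit_spec(cov, y, offset, current.spec.without(t),
                                start_theta=current.theta)
            except Exception as exc:
                raise RuntimeError(
                    f"fit failed while evaluating removal of {t!r} at step {step}: {exc}"
                ) from exc
            candidates.append((t, cand))
        if not candidates:
            break
        best_bic = min(c.bic for _, c in candidates)
        if best_bic >= current.bic:
            break
        tied = [(t, c) for t, c in candidates if c.bic - best_bic <= tie_tol]
        if len(tied) > 1:
            def zscore(item):
                t, _ = item
                cols = ([f"aspect:{l}" for l in ("S", "E", "W")] if t == "aspect"
                        else [t])
                z = (current.params[cols].abs() / current.bse[cols]).max()
                return z
            tied.sort(key=zscore)
        removed, new_fit = tied[0]
        shared = [c for c in new_fit.params.index if c in current.params.index]
        denom = current.params[shared].abs().replace(0, np.nan)
        rel = ((new_fit.params[shared] - current.params[shared]).abs() / denom).max()
        trace.append({"step": step, "removed": removed, "bic": new_fit.bic,
                      "n_terms": len(new_fit.spec),
                      "max_rel_coef_change": float(rel) if np.isfinite(rel) else np.nan})
        current = new_fit
    return current, pd.DataFrame(trace)


def gof_deviance(fit: ModelFit):
    """Residual-deviance goodness-of-fit test.

    Statistic = sum of squared deviance residuals, df = residual degrees of
    freedom, p from the chi-square upper tail.  Small p flags lack of fit.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    stat = fit.deviance
    df = fit.df_resid
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def morans_i(residuals, centers, radius_km: float = 200.0,
             row_standardize: bool = False, flag_threshold: float = 0.20):
    """Moran's I of residuals with binary distance-band weights.

    ``w_ij = 1`` iff ``0 < d(center_i, center_j) <= radius_km`` (radius
    inclusive); an optional row-standardised variant divides each row by
    its neighbour count.  Returns ``(I, flagged)`` with
    ``flagged = I > flag_threshold`` marking problematic residual
    autocorrelation.
    """
    z = np.asarray(residuals, dtype=float)
    pts = np.asarray(centers, dtype=float)
    n = len(z)
    if n < 2:
        raise ValueError("Moran's I requires at least 2 units")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    W = ((d > 0) & (d <= radius_km)).astype(float)
    if W.sum() == 0:
        raise ValueError(f"no neighbour pairs within {radius_km} km")
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
    zc = z - z.mean()
    num = zc @ W @ zc
    I = (n / W.sum()) * num / (zc @ zc)
    return float(I), bool(I > flag_threshold)
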