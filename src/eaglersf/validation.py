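"""Utilization-bin validation against held-out survey years.

Units are ranked by model prediction into 10 equal-count bins (bin 10 =
top decile of predicted use).  Each bin's utilization is its median
prediction normalised over bins,

    U(x_i) = w(x_i) / sum_k w(x_k),

and the expected detection-adjusted count in bin i for held-out year j is
N_ij = N_.j * U(x_i), where N_.j is that year's adjusted total.  Observed
(adjusted, unrounded) sums per bin are compared to expected by ordinary
least squares pooled over years — a well-calibrated model gives an
intercept of 0 and a slope of 1, judged by 90% confidence intervals — and
by Spearman rank correlation computed per year.  By default both axes are
expressed as proportions of the year total (so pooling years is
scale-free); a raw-count mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

N_BINS = 10


def bin_utilization(predictions) -> pd.DataFrame:
    """Rank units into 10 equal-count bins and compute utilizations.

    ``predictions`` is a Series (indexed by unit) or array of finite
    predicted intensities.  Returns a frame indexed by bin 1..10 with the
    unit count, median prediction ``w`` and utilization ``U`` (summing to
    1).  Ties are broken by stable unit order.
    """
    pred = pd.Series(predictions).astype(float)
    if len(pred) < N_BINS:
        raise ValueError(f"need at least {N_BINS} units to form bins, got {len(pred)}")
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictions must be finite")
    order = np.argsort(pred.to_numpy(), kind="stable")
    chunks = np.array_split(order, N_BINS)
    rows = []
    for b, idx in enumerate(chunks, start=1):
        w = float(np.median(pred.to_numpy()[idx]))
        rows.append({"bin": b, "n_units": len(idx), "w": w})
    out = pd.DataFrame(rows).set_index("bin")
    out["U"] = out["w"] / out["w"].sum()
    return out


def assign_bins(predictions) -> pd.Series:
    """Bin label (1..10) per unit under the same ranking as bin_utilization."""
    pred = pd.Series(predictions).astype(float)
    order = np.argsort(pred.to_numpy(), kind="stable")
    labels = np.empty(len(pred), dtype=int)
    for b, idx in enumerate(np.array_split(order, N_BINS), start=1):
        labels[idx] = b
    return pd.Series(labels, index=pred.index, name="bin")


def expected_counts(U: pd.Series, totals: pd.Series) -> pd.DataFrame:
    """Expected adjusted counts per bin and year: N_ij = N_.j * U_i.

    Column sums reproduce the year totals exactly.
    """
    U = pd.Series(U).astype(float)
    totals = pd.Series(totals).astype(float)
    if (totals < 0).any():
        raise ValueError("year totals must be non-negative")
    return pd.DataFrame({yr: tot * U for yr, tot in totals.items()})


@dataclass
class ValidationResult:
    bins: pd.DataFrame            # per-bin w, U, observed & expected per year
    intercept: float
    slope: float
    ci_intercept: tuple
    ci_slope: tuple
    passed: bool
    spearman: dict                # year -> r_s
    mode: str


def validate_regression(observed: pd.DataFrame, U: pd.Series,
                        mode: str = "proportion", alpha: float = 0.10) -> ValidationResult:
    """Observed-vs-expected regression and per-year rank correlation.

    ``observed`` holds the detection-adjusted (unrounded) sums per bin
    (rows, index 1..10) and held-out year (columns).  Pass criterion: the
    90% CI of the intercept contains 0 and that of the slope contains 1.
    """
    obs = observed.astype(float)
    totals = obs.sum(axis=0)
    exp = expected_counts(U, totals)
    if mode == "proportion":
        x = pd.concat([exp[c] / totals[c] for c in exp.columns], ignore_index=True)
        ydat = pd.concat([obs[c] / totals[c] for c in obs.columns], ignore_index=True)
    elif mode == "count":
        x = pd.concat([exp[c] for c in exp.columns], ignore_index=True)
        ydat = pd.concat([obs[c] for c in obs.columns], ignore_index=True)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'proportion' or 'count'")
    if x.std(ddof=0) <= 1e-10 * (1.0 + abs(x.mean())):
        raise ValueError("expected values have zero variance; regression undefined")
    X = sm.add_constant(x.to_numpy(), has_constant="add")
    ols = sm.OLS(ydat.to_numpy(), X).fit()
    ci = ols.conf_int(alpha=alpha)
    ci_int, ci_slope = tuple(ci[0]), tuple(ci[1])
    passed = (ci_int[0] <= 0.0 <= ci_int[1]) and (ci_slope[0] <= 1.0 <= ci_slope[1])
    spearman = {}
    for c in obs.columns:
        r, _ = stats.spearmanr(exp[c], obs[c])
        spearman[c] = float(r)
    bins = pd.DataFrame({"U": U})
    for c in obs.columns:
        bins[f"observed_{c}"] = obs[c]
        bins[f"expected_{c}"] = exp[c]
    return ValidationResult(
        bins=bins,
        intercept=float(ols.params[0]), slope=float(ols.params[1]),
        ci_intercept=ci_int, ci_slope=ci_slope, passed=bool(passed),
        spearman=spearman, mode=mode,
    )
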