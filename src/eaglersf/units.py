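"""Sampling-unit construction along transects.

Units are 2 km x 10 km rectangles centred on points drawn uniformly (with
replacement) along the primary transects.  A draw only becomes a unit if
its full 10-km east-west extent lies inside its transect; draws near
transect ends are discarded.  Because sampling is with replacement,
duplicate and overlapping units are legal and analysed as independent
draws.  Effort per unit is the number of survey years its transect was
actually flown.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def sample_units(transects: pd.DataFrame, n_points: int, seed: int,
                 unit_length_km: float = 10.0, unit_width_km: float = 2.0) -> pd.DataFrame:
    """Random with-replacement point sample along transects -> retained units.

    Returns a frame indexed by unit_id with transect_id, x_center, y,
    x_start, x_end.  Retained count is <= n_points (end draws discarded).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    lengths = transects["length_km"].to_numpy(dtype=float)
    total = lengths.sum()
    if not (lengths > unit_length_km).any():
        raise ValueError(
            f"all transects are shorter than one unit length ({unit_length_km} km); cannot sample units")
    rng = np.random.default_rng(seed)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.uniform(0.0, total, size=n_points)
    ti = np.searchsorted(cum, u, side="right") - 1
    ti = np.clip(ti, 0, len(lengths) - 1)
    half = unit_length_km / 2.0
    rows = []
    uid = 0
    xs = transects["x_start"].to_numpy()
    xe = transects["x_end"].to_numpy()
    ys = transects["y"].to_numpy()
    tids = transects["transect_id"].to_numpy()
    for k in range(n_points):
        i = ti[k]
        x = xs[i] + (u[k] - cum[i])
        if x - half >= xs[i] - 1e-9 and x + half <= xe[i] + 1e-9:
            rows.append({"unit_id": uid, "transect_id": tids[i], "x_center": x,
                         "y": ys[i], "x_start": x - half, "x_end": x + half})
            uid += 1
    df = pd.DataFrame(rows, columns=["unit_id", "transect_id", "x_center", "y",
                                     "x_start", "x_end"]).set_index("unit_id")
    df["width_km"] = unit_width_km
    return df


def assign_observations(obs: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """Attach observations to every unit instance containing them.

    Membership is by along-transect interval: an observation at x on
    transect t falls in a unit iff the unit is on t and
    x in [x_start, x_end).  Overlapping/duplicate units each receive their
    own copy of the observation (each unit is its own independent draw).
    """
    out = []
    by_t = {t: g for t, g in units.reset_index().groupby("transect_id")}
    for t, grp in obs.groupby("transect_id"):
        if t not in by_t:
            continue
        u = by_t[t]
        xvals = grp["x"].to_numpy()
        for urow in u.itertuples(index=False):
            mask = (xvals >= urow.x_start) & (xvals < urow.x_end)
            if mask.any():
                sub = grp.loc[mask].copy()
                sub["unit_id"] = urow.unit_id
                out.append(sub)
    if not out:
        return obs.iloc[0:0].assign(unit_id=pd.Series(dtype=int))
    return pd.concat(out, ignore_index=True)


def assign_effort(units: pd.DataFrame, flown_log: pd.DataFrame,
                  min_years: int = 2) -> pd.DataFrame:
    """Attach per-unit effort (years flown) and drop under-surveyed units.

    A year counts toward a unit's effort iff its transect was flown that
    year (dropout is whole-transect, so a flown transect-year covers the
    unit's full extent).  Units with effort below ``min_years`` are
    excluded from modelling (study floor: 2 of 5 years).
    """
    if len(flown_log) == 0:
        warnings.warn("empty flown-segment log: all units excluded", stacklevel=2)
        out = units.copy()
        out["n_years"] = 0
        return out.iloc[0:0]
    eff = (flown_log[flown_log["flown"]]
           .groupby("transect_id")["year"].nunique())
    out = units.copy()
    out["n_years"] = out["transect_id"].map(eff).fillna(0).astype(int)
    return out[out["n_years"] >= min_years]
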