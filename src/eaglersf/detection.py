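"""Detection-probability adjustment of observed eagle groups.

Aerial line-transect observers miss a known, stratum-specific fraction of
golden eagle groups.  Each detected group is therefore inflated by the
reciprocal of its stratum's mean detection probability (a Horvitz-Thompson
style correction), the inflated values are summed per sampling unit across
survey years, and the sums are rounded to integer *pseudocounts* suitable
for count regression.

Detection strata are the cross of observation type (perched at 107 m AGL,
perched at 150 m AGL, or flying) and observer position in the aircraft
(back-left, combined right, or front-right).  The probabilities themselves
are exogenous inputs estimated from a separate mark-recapture/distance
analysis; this module only consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

OBS_TYPES = ("perched107", "perched150", "flying")
POSITIONS = ("back-left", "right", "front-right")

#: published mean detection probabilities (SE) per stratum, estimated from
#: the 2006-2013 surveys; consumed as data, never re-estimated here.
_STANDARD_TABLE = {
    ("perched107", "back-left"): (0.467, 0.026),
    ("perched107", "right"): (0.588, 0.029),
    ("perched107", "front-right"): (0.456, 0.026),
    ("perched150", "back-left"): (0.280, 0.047),
    ("perched150", "right"): (0.396, 0.051),
    ("perched150", "front-right"): (0.280, 0.045),
    ("flying", "back-left"): (0.380, 0.066),
    ("flying", "right"): (0.472, 0.058),
    ("flying", "front-right"): (0.301, 0.038),
}


class DetectionTable:
    """Mean detection probability and its SE for all nine survey strata.

    Parameters
    ----------
    table : mapping ``(obs_type, position) -> (p_bar, se)``
        Must contain every combination of :data:`OBS_TYPES` and
        :data:`POSITIONS`, with ``0 < p_bar <= 1`` and ``se >= 0``.
    two_observer : bool
        If True, right-side observations use the front-right stratum
        (the two-observer crew configuration); otherwise the combined
        right-side probability is used.
    """

    def __init__(self, table: dict, two_observer: bool = False):
        for ot in OBS_TYPES:
            for pos in POSITIONS:
                if (ot, pos) not in table:
                    raise KeyError(f"detection table missing stratum ({ot!r}, {pos!r})")
        for (ot, pos), (p, se) in table.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"p_bar for ({ot!r}, {pos!r}) must be in (0, 1], got {p}")
            if se < 0:
                raise ValueError(f"se for ({ot!r}, {pos!r}) must be >= 0, got {se}")
        self._table = {k: (float(p), float(se)) for k, (p, se) in table.items()}
        self.two_observer = bool(two_observer)

    @classmethod
    def standard(cls, two_observer: bool = False) -> "DetectionTable":
        """The published nine-stratum table used throughout the survey."""
        return cls(dict(_STANDARD_TABLE), two_observer=two_observer)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, two_observer: bool = False) -> "DetectionTable":
        """Build from a frame with columns obs_type, position, p_bar, se."""
        table = {
            (r.obs_type, r.position): (r.p_bar, r.se)
            for r in df.itertuples(index=False)
        }
        return cls(table, two_observer=two_observer)

    @classmethod
    def from_csv(cls, path, two_observer: bool = False) -> "DetectionTable":
        return cls.from_frame(pd.read_csv(path), two_observer=two_observer)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"obs_type": ot, "position": pos, "p_bar": p, "se": se}
            for (ot, pos), (p, se) in sorted(self._table.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def position_for_side(self, side: str) -> str:
        """Map an aircraft side to the observer-position stratum."""
        if side == "left":
            return "back-left"
        if side == "right":
            return "front-right" if self.two_observer else "right"
        raise KeyError(f"unknown aircraft side {side!r}; expected 'left' or 'right'")

    def prob(self, obs_type: str, side: str) -> float:
        """Mean detection probability for an observation's stratum."""
        key = (obs_type, self.position_for_side(side))
        if key not in self._table:
            raise KeyError(f"no detection stratum for (obs_type={key[0]!r}, position={key[1]!r})")
        return self._table[key][0]

    def se(self, obs_type: str, side: str) -> float:
        key = (obs_type, self.position_for_side(side))
        return self._table[key][1]

    def stratum_key(self, obs_type: str, side: str) -> tuple:
        if obs_type not in OBS_TYPES:
            raise KeyError(f"unknown observation type {obs_type!r}; expected one of {OBS_TYPES}")
        return (obs_type, self.position_for_side(side))

    @property
    def strata(self) -> list:
        """Stratum keys in a fixed, reproducible order."""
        return [(ot, pos) for ot in OBS_TYPES for pos in POSITIONS]

    def prob_vector(self, rng: np.random.Generator | None = None,
                    floor: float = 0.01) -> pd.Series:
        """Per-stratum probabilities, optionally resampled for the bootstrap.

        With ``rng`` given, each stratum's probability is drawn from a
        normal centred on its mean with its SE, truncated to
        ``(floor, 1]`` — one draw per stratum, representing uncertainty in
        the stratum mean rather than per-observation noise.
        """
        idx = pd.MultiIndex.from_tuples(self.strata, names=["obs_type", "position"])
        means = np.array([self._table[k][0] for k in self.strata])
        if rng is None:
            return pd.Series(means, index=idx)
        ses = np.array([self._table[k][1] for k in self.strata])
        out = means.copy()
        for i, (m, s) in enumerate(zip(means, ses)):
            if s > 0:
                from scipy.stats import truncnorm
                a, b = (floor - m) / s, (1.0 - m) / s
                out[i] = truncnorm.rvs(a, b, loc=m, scale=s, random_state=rng)
        return pd.Series(out, index=idx)


def inflate_observation(group_size: int, obs_type: str, side: str,
                        table: DetectionTable) -> float:
    """Detection-adjusted contribution of one observed group.

    Returns ``group_size / p_bar`` for the group's stratum — e.g. a flying
    group of one seen by the back-left observer contributes
    1/0.380 = 2.6316 eagles.  Always at least ``group_size``.
    """
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    p = table.prob(obs_type, side)
    return group_size / p


def round_half_away(x: np.ndarray | float):
    """Round half away from zero (so 7.5 -> 8, -7.5 -> -8).

    Plain arithmetic rounding of non-negative adjusted sums; kept separate
    so the rounding rule is explicit and swappable.
    """
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def stratum_group_matrix(obs: pd.DataFrame, unit_index: pd.Index,
                         table: DetectionTable) -> pd.DataFrame:
    """Summed group sizes per (unit, detection stratum).

    ``obs`` needs columns unit_id, group_size, obs_type, side.  The result
    is a units x 9 matrix G such that the detection-adjusted sum per unit is
    ``G @ (1/p)`` for any stratum probability vector p — the workhorse for
    both the point adjustment and the bootstrap's probability redraws.
    """
    cols = pd.MultiIndex.from_tuples(table.strata, names=["obs_type", "position"])
    G = pd.DataFrame(0.0, index=unit_index, columns=cols)
    if len(obs) == 0:
        return G
    unknown = set(obs["unit_id"]) - set(unit_index)
    if unknown:
        raise KeyError(f"observations reference unknown unit(s): {sorted(unknown)[:5]}")
    keys = [table.stratum_key(ot, sd) for ot, sd in zip(obs["obs_type"], obs["side"])]
    tmp = obs[["unit_id", "group_size"]].copy()
    tmp["stratum"] = keys
    agg = tmp.groupby(["unit_id", "stratum"])["group_size"].sum()
    for (uid, stratum), total in agg.items():
        G.loc[uid, stratum] += total
    return G


def accumulate_units(obs: pd.DataFrame, table: DetectionTable,
                     units: pd.DataFrame) -> pd.DataFrame:
    """Detection-adjusted sums and rounded pseudocounts per sampling unit.

    Parameters
    ----------
    obs : frame with unit_id, group_size, obs_type, side
        All detected groups assigned to units (a group may appear once per
        containing unit instance when units overlap).
    table : DetectionTable
    units : frame indexed by unit_id with an ``n_years`` effort column

    Returns
    -------
    frame indexed by unit_id with raw_sum, pseudocount, n_years.  Units
    with no observations get zeros.
    """
    if "n_years" not in units.columns:
        raise KeyError("units frame must carry an 'n_years' effort column")
    G = stratum_group_matrix(obs, units.index, table)
    inv_p = 1.0 / table.prob_vector().to_numpy()
    raw = G.to_numpy() @ inv_p
    out = pd.DataFrame(
        {
            "raw_sum": raw,
            "pseudocount": round_half_away(raw).astype(int),
            "n_years": units["n_years"].to_numpy(),
        },
        index=units.index,
    )
    return out
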