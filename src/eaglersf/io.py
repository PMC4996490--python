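"""Plain-text serialisation: GeoJSON geometries, CSV tables, JSON fits."""

from __future__ import annotations

import json

import pandas as pd


def transects_to_geojson(transects: pd.DataFrame, path=None):
    """Transects as a GeoJSON FeatureCollection of LineStrings (planar km)."""
    features = []
    for t in transects.itertuples(index=False):
        features.append({
            "type": "Feature",
            "properties": {"transect_id": int(t.transect_id),
                           "length_km": float(t.length_km)},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(t.x_start), float(t.y)],
                                         [float(t.x_end), float(t.y)]]},
        })
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def units_to_geojson(units: pd.DataFrame, path=None, half_width_km: float = 1.0):
    """Sampling units as GeoJSON Polygons (2 x 10-km rectangles)."""
    features = []
    for uid, u in units.iterrows():
        x0, x1 = float(u.x_start), float(u.x_end)
        y0, y1 = float(u.y) - half_width_km, float(u.y) + half_width_km
        props = {"unit_id": int(uid), "transect_id": int(u.transect_id)}
        if "n_years" in units.columns:
            props["n_years"] = int(u.n_years)
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "Polygon",
                         "coordinates": [[[x0, y0], [x1, y0], [x1, y1],
                                          [x0, y1], [x0, y0]]]},
        })
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def fit_to_json(fit, path=None):
    """Serialise a ModelFit summary (coefficients, theta, BIC, ...)."""
    d = fit.to_dict()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
    return d
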