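"""Panel readers/writers and GeoJSON export.

A county panel is a CSV with one row per (unit, year): ``unit_id``, planar
coordinates ``u``/``v`` (projected distance units — do not feed raw
lon/lat, the spatial stages measure Euclidean distance), a ``year`` column,
and outcome/covariate columns.  Death and infant-mortality rates are on the
per-mille scale throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import IntegrityError

__all__ = ["read_panel", "write_panel", "panel_to_geojson", "per_thousand"]

REQUIRED_COLUMNS = ("unit_id", "u", "v", "year")


def read_panel(path, required_value_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read and validate a county panel CSV.

    Raises :class:`IntegrityError` naming the offending rows for duplicate
    (unit, year) pairs or missing coordinates.
    """
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise IntegrityError(f"panel missing required columns: {sorted(missing)}")
    missing_vals = set(required_value_columns) - set(df.columns)
    if missing_vals:
        raise IntegrityError(f"panel missing value columns: {sorted(missing_vals)}")
    dup = df.duplicated(subset=["unit_id", "year"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise IntegrityError(f"duplicate (unit_id, year) at CSV line(s) {rows}")
    bad_coord = df[["u", "v"]].isna().any(axis=1) | ~np.isfinite(df[["u", "v"]]).all(axis=1)
    if bad_coord.any():
        rows = (df.index[bad_coord] + 2).tolist()
        raise IntegrityError(f"missing or non-finite coordinates at CSV line(s) {rows}")
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def per_thousand(totals: np.ndarray, populations: np.ndarray) -> np.ndarray:
    """Resource-per-1,000-persons indicator: ``totals / population × 1000``."""
    return np.asarray(totals, dtype=float) / np.asarray(populations, dtype=float) * 1000.0


def panel_to_geojson(df: pd.DataFrame, path, cell_size: float | None = None,
                     properties: tuple[str, ...] | None = None) -> None:
    """Write units as square grid-cell polygons with attached properties.

    ``cell_size`` defaults to the minimum positive coordinate step.  Useful
    for inspecting LISA labels or coefficient surfaces in any GIS viewer.
    """
    if cell_size is None:
        for col in ("u", "v"):
            vals = np.sort(df[col].unique())
            steps = np.diff(vals)
            steps = steps[steps > 0]
            if len(steps):
                cell_size = float(steps.min())
                break
        else:
            cell_size = 1.0
    h = cell_size / 2.0
    if properties is None:
        properties = tuple(c for c in df.columns if c not in ("u", "v"))
    features = []
    for _, row in df.iterrows():
        u, v = float(row["u"]), float(row["v"])
        ring = [[u - h, v - h], [u + h, v - h], [u + h, v + h], [u - h, v + h], [u - h, v - h]]
        props = {}
        for c in properties:
            val = row[c]
            props[c] = val.item() if isinstance(val, np.generic) else val
        features.append({"type": "Feature",
                         "geometry": {"type": "Polygon", "coordinates": [ring]},
                         "properties": props})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
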