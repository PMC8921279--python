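"""Plain-text geodata exchange: ESRI ASCII grids, GeoJSON, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_ascii_grid(path, values: np.ndarray, cell_size_m: float = 100.0,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost)."""
    values = np.asarray(values, dtype=float)
    nrow, ncol = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\nnrows {nrow}\n")
        fh.write(f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n")
        fh.write(f"cellsize {cell_size_m}\nNODATA_value {nodata}\n")
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid back into (array, header)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    arr = np.loadtxt(lines[6:])
    arr = np.atleast_2d(arr)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def write_geojson(path, geometries: dict, properties: dict | None = None) -> None:
    """Write named shapely geometries as a GeoJSON FeatureCollection."""
    import shapely

    feats = []
    for name, geom in geometries.items():
        props = {"name": str(name)}
        if properties and name in properties:
            props.update(properties[name])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": shapely.geometry.mapping(geom)})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_geojson(path) -> dict:
    """Read a GeoJSON FeatureCollection into {name: shapely geometry}."""
    import shapely

    data = json.loads(Path(path).read_text())
    out = {}
    for i, feat in enumerate(data["features"]):
        name = feat.get("properties", {}).get("name", str(i))
        out[name] = shapely.geometry.shape(feat["geometry"])
    return out
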