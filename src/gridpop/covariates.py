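"""Building-footprint attribute summaries, settlement classification and
covariate screening.

Covariates in the density model are morphological/topological summaries of
building footprints: mean footprint area, mean proximity (inverse of the mean
distance to the nearest footprint), and the mean footprint count within a
focal window. Summaries are computed per zone (microcensus cluster or ~100 m
grid cell) and scaled with grid-level constants so that cluster-level and
cell-level covariates share a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "summarize_footprints",
    "focal_summary",
    "classify_settlement",
    "select_covariates",
    "scale_covariates",
    "CovariateScaler",
]

M2_PER_HA = 10_000.0

#: 8-neighbour connectivity used for settlement components (contour-like).
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def summarize_footprints(footprints, zones) -> pd.DataFrame:
    """Summarize building-footprint polygons within zones.

    Parameters
    ----------
    footprints : sequence of shapely Polygons
    zones : mapping of zone id -> shapely Polygon
        Footprints are assigned to the zone containing their centroid.

    Returns
    -------
    DataFrame indexed by zone id with columns ``building_count``,
    ``total_area_ha``, ``mean_area_ha``, ``mean_perimeter_m``,
    ``mean_nearest_distance_m``, ``mean_proximity`` (1/m) and coefficients of
    variation ``cv_area``, ``cv_perimeter``. Empty zones have zero counts and
    NaN means.
    """
    import shapely

    fps = list(footprints)
    for g in fps:
        if g.is_empty or not g.is_valid:
            raise ValueError("invalid or empty footprint geometry")
    centroids = [g.centroid for g in fps]
    rows = {}
    for zid, zone in zones.items():
        idx = [i for i, c in enumerate(centroids) if zone.covers(c)]
        n = len(idx)
        if n == 0:
            rows[zid] = dict(
                building_count=0, total_area_ha=0.0, mean_area_ha=np.nan,
                mean_perimeter_m=np.nan, mean_nodes=np.nan,
                mean_nearest_distance_m=np.nan,
                mean_proximity=np.nan, cv_area=np.nan, cv_perimeter=np.nan,
            )
            continue
        areas = np.array([fps[i].area for i in idx]) / M2_PER_HA
        perims = np.array([fps[i].length for i in idx])
        # vertex count per polygon (closing point excluded); an available
        # attribute, unused by the default covariate set
        nodes = np.array([len(fps[i].exterior.coords) - 1 for i in idx])
        # centroid-to-centroid nearest-feature distance within the zone
        if n >= 2:
            pts = np.array([[centroids[i].x, centroids[i].y] for i in idx])
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            nearest = np.sqrt(d2.min(axis=1))
            mean_nearest = float(nearest.mean())
            proximity = 1.0 / mean_nearest if mean_nearest > 0 else np.nan
        else:
            mean_nearest = np.nan
            proximity = np.nan
        rows[zid] = dict(
            building_count=n,
            total_area_ha=float(areas.sum()),
            mean_area_ha=float(areas.mean()),
            mean_perimeter_m=float(perims.mean()),
            mean_nodes=float(nodes.mean()),
            mean_nearest_distance_m=mean_nearest,
            mean_proximity=proximity,
            cv_area=float(areas.std() / areas.mean()) if areas.mean() > 0 else np.nan,
            cv_perimeter=float(perims.std() / perims.mean()) if perims.mean() > 0 else np.nan,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def focal_summary(values: np.ndarray, window_m: float, cell_size_m: float = 100.0,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Mean of ``values`` over a square focal window centred on each cell.

    The window spans ``window_m`` metres; edge cells average over the cells
    available inside the grid. ``mask`` restricts the average to selected
    cells (e.g. settled cells); by default every in-grid cell counts.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D raster")
    half = int(round(window_m / 2.0 / cell_size_m))
    if half < 1 and window_m < cell_size_m:
        raise ValueError("focal window smaller than one cell")
    size = 2 * half + 1
    if mask is None:
        mask = np.ones_like(values, dtype=float)
    else:
        mask = np.asarray(mask, dtype=float)
    num = ndimage.uniform_filter(values * mask, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(mask, size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def classify_settlement(footprint_area_ha: np.ndarray, building_count: np.ndarray,
                        settled: np.ndarray | None = None,
                        area_threshold_ha: float = 40.0,
                        count_threshold: int = 13) -> np.ndarray:
    """Label settled cells urban (1) or rural (0); unsettled cells get -1.

    A connected component (8-neighbour) of settled cells is urban when its
    total footprint area is at least ``area_threshold_ha`` and it contains at
    least ``count_threshold`` building footprints; every other settled cell
    is rural.
    """
    area = np.asarray(footprint_area_ha, dtype=float)
    count = np.asarray(building_count, dtype=float)
    if settled is None:
        settled = area > 0
    settled = np.asarray(settled, dtype=bool)
    labels, n = ndimage.label(settled, structure=_STRUCTURE_8)
    out = np.full(area.shape, -1, dtype=np.int8)
    out[settled] = 0
    if n:
        comp_area = ndimage.sum_labels(area, labels, index=np.arange(1, n + 1))
        comp_count = ndimage.sum_labels(count, labels, index=np.arange(1, n + 1))
        urban_comp = (comp_area >= area_threshold_ha) & (comp_count >= count_threshold)
        urban_mask = np.zeros(n + 1, dtype=bool)
        urban_mask[1:] = urban_comp
        out[urban_mask[labels] & settled] = 1
    return out


def select_covariates(candidates: pd.DataFrame, log_density: np.ndarray,
                      top_n: int = 5,
                      collinearity_threshold: float = 0.8,
                      circular: tuple[str, ...] = ("building_count",)) -> dict:
    """Screen candidate covariates against observed log population densities.

    Ranks candidates by |Pearson r| with log-density, keeps the ``top_n``
    strongest, then greedily drops candidates whose pairwise |r| with a
    better-ranked kept candidate reaches ``collinearity_threshold``.
    Candidates named in ``circular`` (used elsewhere in the model, e.g. the
    building count feeding the settlement classification) are excluded up
    front, as are zero-variance candidates.

    Returns a report dict with keys ``ranking`` (name -> r), ``selected``,
    and ``dropped`` (name -> reason).
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least two candidate covariates")
    y = np.asarray(log_density, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least three observations")
    dropped: dict[str, str] = {}
    ranking: dict[str, float] = {}
    usable = []
    for name in candidates.columns:
        x = candidates[name].to_numpy(dtype=float)
        if name in circular:
            dropped[name] = "circular: used elsewhere in the model"
            continue
        if np.std(x) == 0:
            dropped[name] = "zero variance: correlation undefined"
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        ranking[name] = r
        usable.append(name)
    usable.sort(key=lambda n: -abs(ranking[n]))
    shortlist = usable[:top_n]
    for name in usable[top_n:]:
        dropped[name] = "below top-%d by |r| with log-density" % top_n
    selected: list[str] = []
    for name in shortlist:
        clash = None
        for kept in selected:
            r_pair = float(np.corrcoef(candidates[name], candidates[kept])[0, 1])
            if abs(r_pair) >= collinearity_threshold:
                clash = (kept, r_pair)
                break
        if clash is None:
            selected.append(name)
        else:
            dropped[name] = f"collinear with {clash[0]} (|r| = {abs(clash[1]):.3f})"
    return {"ranking": ranking, "selected": selected, "dropped": dropped}


@dataclass(frozen=True)
class CovariateScaler:
    """Grid-level mean/sd constants applied to cells *and* clusters alike."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, values: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(values, pd.DataFrame):
            values = values[list(self.names)].to_numpy(dtype=float)
        return scale_covariates(values, self.mean, self.sd)


def scale_covariates(values: np.ndarray, grid_mean: np.ndarray, grid_sd: np.ndarray) -> np.ndarray:
    """z = (x - grid_mean) / grid_sd with grid-level constants."""
    grid_sd = np.asarray(grid_sd, dtype=float)
    if np.any(grid_sd <= 0):
        raise ValueError("grid-level standard deviation must be positive")
    return (np.asarray(values, dtype=float) - np.asarray(grid_mean, dtype=float)) / grid_sd


def fit_scaler(grid, names) -> CovariateScaler:
    """Compute grid-level scaling constants over settled cells of a world grid."""
    settled = grid["settled"].values.astype(bool)
    cols = []
    for n in names:
        cols.append(grid[n].values[settled])
    mat = np.column_stack(cols)
    mean = np.nanmean(mat, axis=0)
    sd = np.nanstd(mat, axis=0)
    return CovariateScaler(tuple(names), mean, sd)
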