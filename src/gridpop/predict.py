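"""Posterior-predictive gridded population estimates and aggregation.

Prediction in unsurveyed cells replaces the per-cluster weighted precision
(which needs a sampling weight) with the pooled stratum scale

    tau_hat_{t,p} = sum_i tau_{t,p,i} sqrt(v_i) / sum_i sqrt(v_i)

over the training clusters of stratum (t, p), then draws, per posterior
sample and cell j,

    Dhat_j ~ LogNormal(Dbar_j, tau_hat_{t,p}),   N_j ~ Poisson(Dhat_j A_j).

Cells without footprints (A_j = 0) are exactly zero. Uncertainty is carried
as per-cell draws so that polygon aggregation can sum within draws before
taking quantiles (sums of cell quantiles would misstate interval widths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .mcmc import PosteriorDraws

__all__ = ["PredictionRaster", "pooled_precision", "predict_cells",
           "apply_agesex", "aggregate"]


@dataclass
class PredictionRaster:
    """Per-cell posterior-predictive summaries (people per ~100 m cell)."""

    summary: xr.Dataset          # mean / median / q025 / q975 over (row, col)
    draws: np.ndarray | None     # (n_cells, n_draws) for settled cells
    cell_index: tuple[np.ndarray, np.ndarray] | None  # rows, cols of settled cells
    log: dict

    def total(self) -> float:
        return float(self.summary["mean"].sum())


def pooled_precision(tau_draws: np.ndarray, v: np.ndarray, t: np.ndarray,
                     p: np.ndarray, n_types: int | None = None,
                     n_provinces: int | None = None) -> tuple[np.ndarray, dict]:
    """Pooled prediction scale tau_hat_{t,p} per posterior draw.

    ``tau_draws`` has shape (n_draws, T, P); v, t, p describe the training
    clusters. Computed literally as the sqrt(v)-weighted average of the
    per-cluster scales tau_{t,p,i} = tau_{t,p} / sqrt(v_i). Strata with no
    training cluster fall back to pooling over the settlement type (logged).
    """
    tau_draws = np.asarray(tau_draws, dtype=float)
    S, T, P = tau_draws.shape
    sqrt_v = np.sqrt(np.asarray(v, dtype=float))
    g = np.asarray(t) * P + np.asarray(p)
    n_tp = np.bincount(g, minlength=T * P).reshape(T, P)
    denom = np.bincount(g, weights=sqrt_v, minlength=T * P).reshape(T, P)
    # numerator per unit tau: sum_i (1/sqrt(v_i)) * sqrt(v_i) = n_tp
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = n_tp / denom
    log = {"empty_strata": []}
    n_t = n_tp.sum(axis=1)
    denom_t = denom.sum(axis=1)
    for tt in range(T):
        for pp in range(P):
            if n_tp[tt, pp] == 0:
                if denom_t[tt] > 0:
                    factor[tt, pp] = n_t[tt] / denom_t[tt]
                    log["empty_strata"].append(
                        {"t": tt, "p": pp, "fallback": "settlement-type pooling"})
                else:
                    factor[tt, pp] = 1.0
                    log["empty_strata"].append({"t": tt, "p": pp,
                                                "fallback": "identity"})
    return tau_draws * factor[None, :, :], log


def _select_draws(draws: PosteriorDraws, n_draws: int | None):
    alpha = draws.stacked("alpha")      # (M, T, L)
    beta = draws.stacked("beta")        # (M, K, T)
    tau = draws.stacked("tau_tp")       # (M, T, P)
    M = alpha.shape[0]
    if n_draws is None or n_draws >= M:
        idx = np.arange(M)
    else:
        idx = np.linspace(0, M - 1, n_draws).round().astype(int)
    return alpha[idx], beta[idx], tau[idx]


def predict_cells(draws: PosteriorDraws, grid: xr.Dataset, scaler, data,
                  n_draws: int | None = 1000, seed: int | None = None,
                  keep_draws: bool = True, chunk: int = 4096) -> PredictionRaster:
    """Posterior-predictive population per grid cell.

    ``data`` is the PreparedData used in fitting; its weights define the
    pooled precision. Covariates are scaled with the SAME grid-level
    constants used in training (``scaler``). Seedable and chunked over cells
    to bound memory.
    """
    rng = np.random.default_rng(seed)
    alpha, beta, tau = _select_draws(draws, n_draws)
    S = alpha.shape[0]
    tau_hat, log = pooled_precision(tau, data.v, data.t, data.p)

    settled = grid["settled"].values.astype(bool)
    a_map = grid["footprint_area"].values
    active = settled & (a_map > 0)
    rr, cc = np.nonzero(active)
    n_cells = len(rr)
    t_j = np.maximum(grid["settlement_type"].values[rr, cc], 0)
    p_j = grid["province"].values[rr, cc]
    l_j = grid["local_area"].values[rr, cc]
    A_j = a_map[rr, cc]
    X_j = scaler.transform(np.column_stack(
        [grid[n].values[rr, cc] for n in scaler.names]))

    shape = settled.shape
    out = {k: np.zeros(shape) for k in ("mean", "median", "q025", "q975")}
    all_draws = np.empty((n_cells, S), dtype=np.float64) if keep_draws else None

    for start in range(0, n_cells, chunk):
        sl = slice(start, min(start + chunk, n_cells))
        tj, pj, lj = t_j[sl], p_j[sl], l_j[sl]
        dbar = (alpha[:, tj, lj]
                + np.einsum("jk,skj->sj", X_j[sl], beta[:, :, tj]))
        scale = tau_hat[:, tj, pj]
        zhat = dbar + scale * rng.standard_normal(dbar.shape)
        lam = np.exp(zhat) * A_j[sl][None, :]
        n_draw = rng.poisson(lam).astype(np.float64)
        if keep_draws:
            all_draws[sl] = n_draw.T
        out["mean"][rr[sl], cc[sl]] = n_draw.mean(axis=0)
        q = np.quantile(n_draw, [0.5, 0.025, 0.975], axis=0)
        out["median"][rr[sl], cc[sl]] = q[0]
        out["q025"][rr[sl], cc[sl]] = q[1]
        out["q975"][rr[sl], cc[sl]] = q[2]

    summary = xr.Dataset(
        {k: (("row", "col"), v) for k, v in out.items()},
        coords=grid.coords, attrs=dict(grid.attrs) | {"n_draws": S},
    )
    return PredictionRaster(summary=summary, draws=all_draws,
                            cell_index=(rr, cc), log=log)


def apply_agesex(pred: PredictionRaster, proportions, grid: xr.Dataset,
                 groups: list | None = None) -> dict:
    """Split per-cell population draws into age-sex groups.

    Multiplies each cell draw by the province's proportion draw of the same
    index (propagating joint uncertainty) and returns per-group summary
    rasters {group: Dataset(mean, q025, q975)}.
    """
    if pred.draws is None:
        raise ValueError("predict_cells must be run with keep_draws=True")
    rr, cc = pred.cell_index
    p_j = grid["province"].values[rr, cc]
    S = pred.draws.shape[1]
    group_index = proportions.group_index
    groups = groups if groups is not None else list(group_index)
    shape = grid["settled"].shape

    provs = np.unique(p_j)
    for p in provs:
        if p not in proportions.draws:
            raise ValueError(f"province {p} has no fitted age-sex proportions")
        if proportions.draws[p].shape[0] < S:
            raise ValueError("need at least as many proportion draws as cell draws")

    out = {}
    for g in groups:
        j = list(group_index).index(tuple(g) if not isinstance(g, tuple) else g)
        pi_gp = np.column_stack(
            [proportions.draws[p][:S, j] for p in provs])   # (S, n_prov)
        prov_pos = np.searchsorted(provs, p_j)
        cell_draws = pred.draws * pi_gp[:, prov_pos].T       # (n_cells, S)
        mean = np.zeros(shape)
        q025 = np.zeros(shape)
        q975 = np.zeros(shape)
        mean[rr, cc] = cell_draws.mean(axis=1)
        q = np.quantile(cell_draws, [0.025, 0.975], axis=1)
        q025[rr, cc] = q[0]
        q975[rr, cc] = q[1]
        out[tuple(g)] = xr.Dataset(
            {"mean": (("row", "col"), mean), "q025": (("row", "col"), q025),
             "q975": (("row", "col"), q975)})
    return out


def aggregate(pred: PredictionRaster, grid: xr.Dataset, polygons: dict) -> pd.DataFrame:
    """Aggregate cell draws to polygons: per-draw sums, then quantiles.

    Cells are assigned by cell-center containment. A polygon with no cells
    (e.g. outside the grid) yields zeros with a warning flag in the output.
    """
    import shapely

    if pred.draws is None:
        raise ValueError("predict_cells must be run with keep_draws=True")
    rr, cc = pred.cell_index
    xs = grid["x"].values[cc]
    ys = grid["y"].values[rr]
    pts = shapely.points(xs, ys)
    rows = []
    for name, poly in polygons.items():
        inside = shapely.contains(poly, pts) | shapely.covers(poly, pts)
        if not inside.any():
            rows.append((name, 0, 0.0, 0.0, 0.0, 0.0, True))
            continue
        sums = pred.draws[inside].sum(axis=0)        # per-draw polygon totals
        q = np.quantile(sums, [0.5, 0.025, 0.975])
        rows.append((name, int(inside.sum()), float(sums.mean()),
                     float(q[0]), float(q[1]), float(q[2]), False))
    return pd.DataFrame(rows, columns=["polygon", "n_cells", "mean", "median",
                                       "q025", "q975", "empty"])
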