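"""Validation machinery: cross-validation, residual metrics, spatial tests.

Goodness of fit is assessed on posterior-predictive cluster draws:
bias (mean residual), imprecision (sd of residuals), inaccuracy (mean
absolute residual), R-squared (squared Pearson correlation of observed vs
posterior-mean predictions), and the percentage of observations inside the
central 95% prediction interval; each metric also has a scaled companion
computed on residual/prediction. Out-of-sample behaviour uses k-fold
cross-validation where every cluster is predicted exactly once by a model
fit without it, with the pooled precision tau_hat standing in for the
cluster's weighted precision. Residual spatial structure is tested with
Moran's I (inverse-distance weights, permutation p-value) and the empirical
semivariogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .mcmc import PosteriorDraws, sample_posterior
from .model import ModelConfig, PreparedData
from .predict import pooled_precision
from .survey import aggregate_agesex

__all__ = [
    "crossvalidate",
    "posterior_predict_clusters",
    "residual_metrics",
    "metrics_table",
    "morans_i",
    "MoranResult",
    "semivariogram",
    "crossvalidate_agesex",
]


def posterior_predict_clusters(draws: PosteriorDraws, train: PreparedData,
                               target: PreparedData, n_draws: int | None = 500,
                               seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-predictive draws of totals and densities for target clusters.

    Uses the pooled stratum scale tau_hat computed from the training
    clusters' weights, so the same machinery serves in-sample and held-out
    prediction. Returns (totals_draws, density_draws), each (I_target, S).
    """
    rng = np.random.default_rng(seed)
    alpha = draws.stacked("alpha")
    beta = draws.stacked("beta")
    tau = draws.stacked("tau_tp")
    M = alpha.shape[0]
    if n_draws is not None and n_draws < M:
        idx = np.linspace(0, M - 1, n_draws).round().astype(int)
        alpha, beta, tau = alpha[idx], beta[idx], tau[idx]
    tau_hat, _ = pooled_precision(tau, train.v, train.t, train.p)

    tj, pj, lj = target.t, target.p, target.l
    dbar = alpha[:, tj, lj] + np.einsum("jk,skj->sj", target.X, beta[:, :, tj])
    scale = tau_hat[:, tj, pj]
    zhat = dbar + scale * rng.standard_normal(dbar.shape)
    dens = np.exp(zhat)
    totals = rng.poisson(dens * target.A[None, :]).astype(float)
    return totals.T, dens.T


@dataclass
class CVResult:
    fold: np.ndarray               # fold id per cluster
    totals_draws: np.ndarray       # (I, S)
    density_draws: np.ndarray      # (I, S)
    log: list


def _make_folds(data: PreparedData, k: int, rng) -> tuple[np.ndarray, list]:
    I = data.n_clusters
    fold = np.empty(I, dtype=int)
    perm = rng.permutation(I)
    for j, idx in enumerate(np.array_split(perm, k)):
        fold[idx] = j
    log = []
    # a fold must not empty any (t, p) stratum of the training set
    g = data.t * data.n_provinces + data.p
    for j in range(k):
        for s in np.unique(g):
            members = np.nonzero(g == s)[0]
            if len(members) and np.all(fold[members] == j):
                move = members[rng.integers(len(members))]
                fold[move] = (j + 1) % k
                log.append({"fold": j, "stratum": int(s),
                            "reassigned_cluster": int(move)})
    return fold, log


def crossvalidate(data: PreparedData, config: ModelConfig | None = None,
                  k: int = 10, seed: int = 0,
                  n_draws_pred: int | None = 500) -> CVResult:
    """k-fold cross-validation of the density model.

    Partitions clusters into k seeded folds (reassigning a cluster when a
    fold would empty a stratum, logged), fits the model k times and predicts
    each held-out cluster from the fit that excluded it.
    """
    if k < 2:
        raise ValueError("need k >= 2")
    if data.n_clusters < k:
        raise ValueError("fewer clusters than folds")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    fold, log = _make_folds(data, k, rng)
    totals = None
    dens = None
    for j in range(k):
        held = fold == j
        train = data.subset(~held)
        test = data.subset(held, renormalize=False)
        draws = sample_posterior(train, config, seed=int(rng.integers(2 ** 31)))
        t_d, d_d = posterior_predict_clusters(
            draws, train, test, n_draws=n_draws_pred,
            seed=int(rng.integers(2 ** 31)))
        if totals is None:
            totals = np.empty((data.n_clusters, t_d.shape[1]))
            dens = np.empty_like(totals)
        totals[held] = t_d
        dens[held] = d_d
    return CVResult(fold=fold, totals_draws=totals, density_draws=dens, log=log)


def residual_metrics(observed, pred_draws, level: float = 0.95,
                     r2_mode: str = "obs_pred") -> dict:
    """Residual metrics of posterior-predictive draws against observations.

    Residual = posterior-mean prediction - observed. Returns bias,
    imprecision (population sd of residuals, so bias^2 + imprecision^2 =
    mean squared residual), inaccuracy, r2, coverage_pct (% of observations
    inside the central ``level`` prediction interval), and scaled companions
    (residual / posterior-mean prediction). ``r2_mode='residuals'`` gives
    the literal squared correlation of residuals with observations instead
    of the conventional observed-vs-predicted correlation.
    """
    obs = np.asarray(observed, dtype=float)
    draws = np.asarray(pred_draws, dtype=float)
    if obs.ndim != 1 or draws.shape[0] != obs.shape[0]:
        raise ValueError("pred_draws must be (n_obs, n_draws)")
    if len(obs) < 3:
        raise ValueError("need at least three observations")
    pred = draws.mean(axis=1)
    resid = pred - obs
    a = (1 - level) / 2
    lo = np.quantile(draws, a, axis=1)
    hi = np.quantile(draws, 1 - a, axis=1)
    coverage = 100.0 * np.mean((obs >= lo) & (obs <= hi))
    out = {
        "bias": float(resid.mean()),
        "imprecision": float(resid.std()),
        "inaccuracy": float(np.abs(resid).mean()),
        "coverage_pct": float(coverage),
    }
    if np.std(obs) == 0 or np.std(pred) == 0:
        out["r2"] = np.nan
        out["r2_defined"] = False
    else:
        if r2_mode == "obs_pred":
            r = np.corrcoef(obs, pred)[0, 1]
        elif r2_mode == "residuals":
            r = np.corrcoef(resid, obs)[0, 1]
        else:
            raise ValueError("r2_mode must be 'obs_pred' or 'residuals'")
        out["r2"] = float(r ** 2)
        out["r2_defined"] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(pred != 0, resid / pred, np.nan)
    scaled = scaled[np.isfinite(scaled)]
    if scaled.size:
        out["scaled_bias"] = float(scaled.mean())
        out["scaled_imprecision"] = float(scaled.std())
        out["scaled_inaccuracy"] = float(np.abs(scaled).mean())
    return out


def metrics_table(entries: dict) -> pd.DataFrame:
    """Assemble metric dicts into a goodness-of-fit table.

    ``entries`` maps (estimate, prediction) -> metrics dict, e.g.
    ("Population totals", "Out-of-sample") -> residual_metrics(...).
    """
    rows = []
    for (estimate, prediction), m in entries.items():
        rows.append({
            "estimate": estimate, "prediction": prediction,
            "bias": m["bias"], "imprecision": m["imprecision"],
            "inaccuracy": m["inaccuracy"], "r2": m["r2"],
            "coverage_pct": m["coverage_pct"],
            "scaled_bias": m.get("scaled_bias", np.nan),
            "scaled_imprecision": m.get("scaled_imprecision", np.nan),
            "scaled_inaccuracy": m.get("scaled_inaccuracy", np.nan),
        })
    return pd.DataFrame(rows)


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p_norm: float
    p_perm: float
    n: int


def _inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    d = squareform(pdist(coords))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if np.isinf(w).any():
        raise ValueError("duplicate coordinates give infinite weights")
    rs = w.sum(axis=1, keepdims=True)
    return w / rs


def morans_i(residuals, coords, n_permutations: int = 999,
             seed: int | None = None) -> MoranResult:
    """Global Moran's I of residuals with row-standardized inverse-distance
    weights; permutation p-value (two-sided) plus the normal approximation.
    """
    x = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 locations")
    if np.std(x) == 0:
        raise ValueError("Moran's I undefined for constant residuals")
    w = _inverse_distance_weights(coords)

    def stat(v):
        z = v - v.mean()
        return n / w.sum() * (z @ w @ z) / (z @ z)

    I_obs = float(stat(x))
    e_i = -1.0 / (n - 1)
    # normal approximation under randomization
    s0 = w.sum()
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=0) + w.sum(axis=1)) ** 2)
    z_c = x - x.mean()
    m2 = np.mean(z_c ** 2)
    m4 = np.mean(z_c ** 4)
    b2 = m4 / m2 ** 2
    var_i = ((n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
              - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
             / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2)) - e_i ** 2
    z_score = (I_obs - e_i) / np.sqrt(var_i)
    p_norm = float(2 * norm.sf(abs(z_score)))

    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = stat(rng.permutation(x))
    p_perm = float((1 + np.sum(np.abs(perms - e_i) >= abs(I_obs - e_i)))
                   / (1 + n_permutations))
    return MoranResult(I=I_obs, expected=e_i, z=float(z_score),
                       p_norm=p_norm, p_perm=p_perm, n=n)


def semivariogram(residuals, coords, bins: int | np.ndarray = 10) -> pd.DataFrame:
    """Empirical semivariogram: gamma(h) = mean squared difference / 2 per
    distance bin, with pair counts. Empty bins are reported with NaN."""
    x = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    d = pdist(coords)
    diffs = pdist(x[:, None], metric="sqeuclidean")
    if np.isscalar(bins):
        edges = np.linspace(0, d.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    if len(edges) < 3:
        raise ValueError("need at least 2 lag bins")
    which = np.digitize(d, edges[1:-1])
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        n_pairs = int(sel.sum())
        gamma = float(diffs[sel].mean() / 2.0) if n_pairs else np.nan
        rows.append(((edges[b] + edges[b + 1]) / 2, edges[b], edges[b + 1],
                     gamma, n_pairs))
    return pd.DataFrame(rows, columns=["lag", "lag_lo", "lag_hi", "gamma",
                                       "n_pairs"])


def crossvalidate_agesex(individuals: pd.DataFrame, k: int = 10, seed: int = 0,
                         n_draws: int = 2000,
                         cluster_col: str = "cluster_id") -> dict:
    """Hold out ~1/k of clusters per province, fit the age-sex posterior on
    the rest, and compare predicted proportion draws with the held-out
    observed proportions. Returns observed (G*P,), predicted draws
    (G*P, S) and the group/province labels."""
    from .agesex import fit_agesex

    if cluster_col not in individuals.columns:
        raise ValueError("individuals need a cluster id column for age-sex CV")
    rng = np.random.default_rng(seed)
    obs_rows, draw_rows, labels = [], [], []
    for p, grp in individuals.groupby("province"):
        clusters = grp[cluster_col].unique()
        rng.shuffle(clusters)
        n_hold = max(1, len(clusters) // k)
        held = set(clusters[:n_hold])
        test = grp[grp[cluster_col].isin(held)]
        train = grp[~grp[cluster_col].isin(held)]
        if len(test) == 0 or len(train) == 0:
            continue
        table = aggregate_agesex(train)
        post = fit_agesex(table, n_draws=n_draws,
                          seed=int(rng.integers(2 ** 31)))
        obs_tab = aggregate_agesex(test)
        obs_prop = obs_tab.counts[p].to_numpy(dtype=float)
        n_test = int(obs_prop.sum())
        obs_prop = obs_prop / n_test
        obs_rows.append(obs_prop)
        # posterior-predictive proportions for a held-out aggregate of the
        # same size: multinomial noise on top of pi uncertainty, mirroring
        # the prediction intervals used for totals and densities
        pp = np.stack([rng.multinomial(n_test, pi) / n_test
                       for pi in post.draws[p]])
        draw_rows.append(pp.T)                 # (G, S)
        labels.extend([(p, sex, ab) for sex, ab in obs_tab.counts.index])
    return {
        "observed": np.concatenate(obs_rows),
        "pred_draws": np.vstack(draw_rows),
        "labels": labels,
    }
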