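"""Synthetic study regions, surveys and age-sex counts with known truth.

The generator emulates the generative structure the density model assumes:
a gridded world of ~100 m cells carrying building-footprint summaries, a
nested hierarchy of settlement type (rural/urban) -> province -> local area,
cluster log-densities drawn from a normal around a linear predictor, Poisson
population counts with footprint area as exposure, population-weighted
cluster sampling with recorded (noisy) weights, and province-level age-sex
counts drawn from a multinomial. Ground-truth parameters are returned so
recovery and bias experiments can score estimates against the truth.

Default sizes mirror the study conditions: 5 provinces, ~7 local areas per
province, 926 clusters of ~3 settled hectares, 7/926 undercounted clusters,
14/926 clusters with no detected footprints, household nonresponse at
629/79126.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage
from scipy.special import expit

from .covariates import classify_settlement, fit_scaler, focal_summary
from .survey import AGE_BIN_EDGES, AGE_BIN_LABELS, GROUP_LABELS, SEXES

__all__ = [
    "WorldConfig",
    "SurveyDesign",
    "SyntheticTruth",
    "SurveyData",
    "COVARIATE_NAMES",
    "generate_world",
    "draw_truth",
    "simulate_survey",
    "default_age_pyramid",
]

#: Covariates used by the default model: mean footprint area, inverse mean
#: nearest-footprint distance, mean footprint count in a ~2 km focal window.
COVARIATE_NAMES: tuple[str, ...] = ("mean_area", "proximity", "focal_count")

SETTLEMENT_TYPES: tuple[str, str] = ("rural", "urban")


@dataclass(frozen=True)
class WorldConfig:
    """Layout and intensity parameters of a synthetic study region."""

    n_provinces: int = 5
    n_localareas_per_province: int = 7
    grid_shape: tuple[int, int] = (120, 120)
    settled_fraction: float = 0.30
    cell_size_m: float = 100.0
    smooth_sigma: float = 2.0
    urban_area_threshold_ha: float = 40.0
    urban_count_threshold: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 1 or self.n_localareas_per_province < 1:
            raise ValueError("need at least one province and local area")
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ValueError("degenerate grid")
        if not (0 < self.settled_fraction <= 1):
            raise ValueError("settled_fraction must lie in (0, 1]")

    @property
    def n_localareas(self) -> int:
        return self.n_provinces * self.n_localareas_per_province


@dataclass(frozen=True)
class SurveyDesign:
    """Cluster sampling design and artifact-injection rates."""

    mode: str = "population_weighted"
    n_clusters: int = 926
    cluster_settled_area_target_ha: float = 3.0
    random_fraction: float = 0.0
    nonresponse_rate: float = 629.0 / 79126.0
    undercount_cluster_rate: float = 7.0 / 926.0
    zero_footprint_rate: float = 14.0 / 926.0
    weight_outlier_rate: float = 0.03
    weight_noise_sd: float = 0.25
    mean_household_size: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "population_weighted"):
            raise ValueError("mode must be 'random' or 'population_weighted'")
        for name in ("random_fraction", "nonresponse_rate", "undercount_cluster_rate",
                     "zero_footprint_rate", "weight_outlier_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a synthetic world."""

    xi_t: np.ndarray          # (T,) settlement-type intercept means
    xi_tp: np.ndarray         # (T, P)
    alpha: np.ndarray         # (T, L) log people per footprint-ha
    beta: np.ndarray          # (K, T) covariate effects on the scaled covariates
    tau: np.ndarray           # (T, P) log-scale sd of cluster densities
    pi: pd.DataFrame          # (G x P) age-sex proportions
    rho: np.ndarray           # (K,)
    omega: np.ndarray         # (K,)
    nu_t: float
    nu_tp: float
    local_province: np.ndarray  # (L,) province of each local area
    covariate_names: tuple[str, ...] = COVARIATE_NAMES

    def __post_init__(self) -> None:
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        sums = self.pi.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("age-sex proportions must sum to one per province")


@dataclass
class SurveyData:
    """Output of a simulated survey."""

    clusters: pd.DataFrame
    households: pd.DataFrame
    individuals: pd.DataFrame
    design: SurveyDesign


# ---------------------------------------------------------------------------
# world


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def generate_world(config: WorldConfig, rng: np.random.Generator | None = None) -> xr.Dataset:
    """Generate a gridded study region with per-cell footprint summaries.

    Returns an xarray Dataset over (row, col) with footprint area (ha per
    cell), building count, mean footprint area (ha), proximity (1/m), the
    2 km focal mean of building count, settlement type, and the nested
    province/local-area labels. Unsettled cells carry zero footprint area.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nrow, ncol = config.grid_shape

    # spatially smooth Gaussian fields, thresholded/transformed to mimic
    # footprint summaries without real imagery
    f_settle = _smooth_field(rng, (nrow, ncol), config.smooth_sigma)
    f_intensity = _smooth_field(rng, (nrow, ncol), config.smooth_sigma * 1.5)
    f_size = _smooth_field(rng, (nrow, ncol), config.smooth_sigma)
    f_dist = _smooth_field(rng, (nrow, ncol), config.smooth_sigma)

    thresh = np.quantile(f_settle, 1.0 - config.settled_fraction)
    settled = f_settle >= thresh

    # footprint area per 1-ha cell: low almost everywhere, high in dense cores
    area_frac = 0.02 + 0.55 * expit(2.5 * (f_intensity - 1.0))
    footprint_area = np.where(settled, area_frac, 0.0)

    mean_area = np.clip(0.008 + 0.004 * f_size, 0.003, None)  # ha per building
    count = np.where(settled, np.maximum(1, np.rint(footprint_area / mean_area)), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_area = np.where(count > 0, footprint_area / count, 0.0)

    # mean nearest-footprint distance ~ 50/sqrt(n) m in a 1-ha cell, noisy
    with np.errstate(divide="ignore"):
        nn_dist = np.where(count > 0, 50.0 / np.sqrt(np.maximum(count, 1))
                           * np.exp(0.2 * f_dist), np.inf)
    proximity = np.where(count > 0, 1.0 / nn_dist, 0.0)

    focal_count = focal_summary(count.astype(float), 2000.0, config.cell_size_m)

    stype = classify_settlement(footprint_area, count, settled,
                                config.urban_area_threshold_ha,
                                config.urban_count_threshold)

    # nested hierarchy: provinces as column strips, local areas as row strips
    cols = np.arange(ncol)
    rows = np.arange(nrow)
    province_of_col = np.minimum(cols * config.n_provinces // ncol,
                                 config.n_provinces - 1)
    local_of_row = np.minimum(rows * config.n_localareas_per_province // nrow,
                              config.n_localareas_per_province - 1)
    province = np.broadcast_to(province_of_col[None, :], (nrow, ncol)).copy()
    local_area = (province * config.n_localareas_per_province
                  + np.broadcast_to(local_of_row[:, None], (nrow, ncol)))

    x = (np.arange(ncol) + 0.5) * config.cell_size_m
    y = (np.arange(nrow) + 0.5) * config.cell_size_m
    ds = xr.Dataset(
        data_vars=dict(
            settled=(("row", "col"), settled),
            footprint_area=(("row", "col"), footprint_area),
            building_count=(("row", "col"), count.astype(np.int32)),
            mean_area=(("row", "col"), mean_area),
            proximity=(("row", "col"), proximity),
            focal_count=(("row", "col"), focal_count),
            settlement_type=(("row", "col"), stype),
            province=(("row", "col"), province.astype(np.int16)),
            local_area=(("row", "col"), local_area.astype(np.int16)),
        ),
        coords=dict(x=("col", x), y=("row", y)),
        attrs=dict(
            cell_size_m=config.cell_size_m,
            cell_area_ha=config.cell_size_m ** 2 / 1e4,
            n_provinces=config.n_provinces,
            n_localareas=config.n_localareas,
            n_localareas_per_province=config.n_localareas_per_province,
        ),
    )
    return ds


# ---------------------------------------------------------------------------
# truth


def default_age_pyramid(rate: float = 0.033) -> np.ndarray:
    """A declining age pyramid: exponential age distribution integrated over
    the 18 standard bins, split 50.5/49.5 female/male. Returns length-36
    proportions in GROUP_LABELS order."""
    edges = np.array(AGE_BIN_EDGES, dtype=float)
    upper = np.where(np.isinf(edges[1:]), 120.0, edges[1:])
    mass = np.exp(-rate * edges[:-1]) - np.exp(-rate * upper)
    mass = mass / mass.sum()
    split = {"female": 0.505, "male": 0.495}
    return np.concatenate([mass * split[s] for s in SEXES])


DEFAULT_TRUTH_HYPERS: dict = {
    # log people per footprint ha; rural densities run higher than urban
    "xi_t": (5.7, 5.2),          # (rural, urban)
    "nu_t": 0.25,                # sd of province means around the type mean
    "nu_tp": 0.20,               # sd of local-area intercepts within province
    # effects of (mean_area, proximity, focal_count) on the scaled covariates
    "rho": (-0.40, 0.20, 0.0),
    "omega": (0.05, 0.15, 0.25),
    "tau_mu": 0.5,               # log-scale sd of cluster densities
    "tau_sd": 0.05,
    "pyramid_concentration": 300.0,
}


def draw_truth(config: WorldConfig, overrides: dict | None = None,
               rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw ground-truth parameters from the nested generative hierarchy.

    ``overrides`` replaces entries of the default hyperparameters (e.g.
    ``{"nu_tp": 0.0}`` collapses local-area intercepts onto the province
    mean). Negative scale overrides are rejected; a zero scale collapses the
    corresponding level.
    """
    hypers = dict(DEFAULT_TRUTH_HYPERS)
    if overrides:
        unknown = set(overrides) - set(hypers)
        if unknown:
            raise ValueError(f"unknown hyperparameter overrides: {sorted(unknown)}")
        hypers.update(overrides)
    for name in ("nu_t", "nu_tp", "tau_sd", "pyramid_concentration"):
        if hypers[name] < 0:
            raise ValueError(f"{name} must be nonnegative")
    if not np.all(np.isfinite(np.concatenate([
            np.atleast_1d(np.asarray(hypers[k], dtype=float))
            for k in ("xi_t", "nu_t", "nu_tp", "rho", "omega", "tau_mu", "tau_sd")]))):
        raise ValueError("hyperparameter overrides must be finite")
    omega = np.asarray(hypers["omega"], dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be nonnegative")
    if hypers["tau_mu"] <= 0:
        raise ValueError("tau_mu must be positive")

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    T, P, Lpp = 2, config.n_provinces, config.n_localareas_per_province
    L = config.n_localareas
    K = len(COVARIATE_NAMES)

    xi_t = np.asarray(hypers["xi_t"], dtype=float)
    xi_tp = xi_t[:, None] + hypers["nu_t"] * rng.standard_normal((T, P))
    local_province = np.repeat(np.arange(P), Lpp)
    alpha = xi_tp[:, local_province] + hypers["nu_tp"] * rng.standard_normal((T, L))
    rho = np.asarray(hypers["rho"], dtype=float)
    beta = rho[:, None] + omega[:, None] * rng.standard_normal((K, T))
    tau = hypers["tau_mu"] + hypers["tau_sd"] * rng.standard_normal((T, P))
    tau = np.abs(tau)
    if np.any(tau <= 0):
        raise ValueError("drawn tau not positive; increase tau_mu")

    base = default_age_pyramid()
    conc = hypers["pyramid_concentration"]
    if conc > 0:
        pi = rng.dirichlet(base * conc, size=P).T
    else:
        pi = np.tile(base[:, None], (1, P))
    pi_df = pd.DataFrame(pi, index=pd.MultiIndex.from_tuples(
        GROUP_LABELS, names=["sex", "age_bin"]), columns=np.arange(P))

    return SyntheticTruth(
        xi_t=xi_t, xi_tp=xi_tp, alpha=alpha, beta=beta, tau=tau, pi=pi_df,
        rho=rho, omega=omega, nu_t=float(hypers["nu_t"]),
        nu_tp=float(hypers["nu_tp"]), local_province=local_province,
    )


# ---------------------------------------------------------------------------
# survey simulation


_NEIGHBOURS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def _grow_cluster(seed_rc, settled, assigned, target_cells):
    """Contiguous settled cells around a seed until the target settled area
    is reached (simplified stand-in for manual cluster delineation)."""
    nrow, ncol = settled.shape
    cells = [seed_rc]
    assigned[seed_rc] = True
    frontier = [seed_rc]
    while len(cells) < target_cells and frontier:
        nxt = []
        for (r, c) in frontier:
            for dr, dc in _NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and settled[rr, cc] \
                        and not assigned[rr, cc]:
                    assigned[rr, cc] = True
                    cells.append((rr, cc))
                    nxt.append((rr, cc))
                    if len(cells) >= target_cells:
                        return cells
        frontier = nxt
    return cells


def simulate_survey(grid: xr.Dataset, truth: SyntheticTruth, design: SurveyDesign,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> SurveyData:
    """Simulate a microcensus survey over a synthetic world.

    For each cluster i the log density is Z_i = alpha[t,p,l] + beta.x + u
    with u ~ N(0, tau[t,p]), D_i = exp(Z_i), and N_i ~ Poisson(D_i A_i).
    Under population-weighted sampling, seed cells are drawn without
    replacement with probability proportional to a noisy population proxy
    (footprint area x exp(predictor + u)); the recorded sampling weight w_i
    is that proxy (times noise and occasional heavy-tailed outlier factors).
    Randomly sampled clusters (mode "random", or the ``random_fraction``
    share emulating a first survey round) have missing weights.

    Injected artifacts -- undercounted clusters (thinned counts) and
    clusters whose footprints went undetected (area zeroed after counts were
    drawn) -- are flagged both in the observable ``undercount`` column and in
    hidden ``truth_*`` columns.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    settled = grid["settled"].values.astype(bool)
    n_settled = int(settled.sum())
    if design.n_clusters > n_settled:
        raise ValueError(
            f"design asks for {design.n_clusters} clusters but the grid has "
            f"only {n_settled} settled cells")

    cell_ha = float(grid.attrs["cell_area_ha"])
    target_cells = max(1, int(np.ceil(design.cluster_settled_area_target_ha / cell_ha)))

    scaler = fit_scaler(grid, truth.covariate_names)
    t_map = grid["settlement_type"].values
    p_map = grid["province"].values
    l_map = grid["local_area"].values
    a_map = grid["footprint_area"].values
    count_map = grid["building_count"].values

    rr, cc = np.nonzero(settled)
    t_cell = np.maximum(t_map[rr, cc], 0)
    cov_cell = np.column_stack([grid[n].values[rr, cc] for n in truth.covariate_names])
    x_cell = scaler.transform(cov_cell)
    dbar_cell = (truth.alpha[t_cell, l_map[rr, cc]]
                 + np.einsum("ik,ki->i", x_cell, truth.beta[:, t_cell]))
    u_cell = rng.standard_normal(len(rr)) * truth.tau[t_cell, p_map[rr, cc]]
    proxy_cell = a_map[rr, cc] * np.exp(dbar_cell + u_cell)

    # seed selection order
    if design.mode == "population_weighted":
        # weighted sampling without replacement (Gumbel-max keys)
        keys = np.log(proxy_cell + 1e-300) + rng.gumbel(size=len(rr))
        order = np.argsort(-keys)
    else:
        order = rng.permutation(len(rr))

    assigned = np.zeros_like(settled)
    clusters = []
    cell_index = {(int(r), int(c)): j for j, (r, c) in enumerate(zip(rr, cc))}
    for j in order:
        if len(clusters) >= design.n_clusters:
            break
        seed_rc = (int(rr[j]), int(cc[j]))
        if assigned[seed_rc]:
            continue
        cells = _grow_cluster(seed_rc, settled, assigned, target_cells)
        clusters.append((j, cells))
    if len(clusters) < design.n_clusters:
        raise ValueError("could not delineate the requested number of clusters")

    n_rand = int(round(design.random_fraction * design.n_clusters))
    if design.mode == "random":
        n_rand = design.n_clusters

    records = []
    hh_rows = []
    for i, (j, cells) in enumerate(clusters):
        idx = np.array([cell_index[c] for c in cells])
        crr = np.array([c[0] for c in cells])
        ccc = np.array([c[1] for c in cells])
        A_i = float(a_map[crr, ccc].sum())
        w_cells = count_map[crr, ccc].astype(float)
        w_cells = np.where(w_cells > 0, w_cells, 1e-9)
        cov_i = {
            "mean_area": float(np.average(grid["mean_area"].values[crr, ccc], weights=w_cells)),
            "proximity": float(np.average(grid["proximity"].values[crr, ccc], weights=w_cells)),
            "focal_count": float(np.mean(grid["focal_count"].values[crr, ccc])),
        }
        t_i = int(max(t_map[cells[0]], 0))
        p_i = int(p_map[cells[0]])
        l_i = int(l_map[cells[0]])
        x_i = scaler.transform(np.array([[cov_i[n] for n in truth.covariate_names]]))[0]
        dbar_i = float(truth.alpha[t_i, l_i] + truth.beta[:, t_i] @ x_i)
        z_i = dbar_i + u_cell[j]          # selection residual carried into density
        d_i = float(np.exp(z_i))
        n_true = int(rng.poisson(d_i * A_i))

        is_random_round = i >= design.n_clusters - n_rand if design.mode != "random" else True
        if is_random_round:
            w_i = np.nan
            outlier = False
        else:
            w_i = float(proxy_cell[j] * np.exp(rng.normal(0.0, design.weight_noise_sd)))
            outlier = bool(rng.random() < design.weight_outlier_rate)
            if outlier:
                w_i *= float(np.exp(rng.normal(2.5, 0.5)))

        records.append(dict(
            cluster_id=i, province=p_i, local_area=l_i, settlement_type=t_i,
            footprint_area=A_i, n_cells=len(cells),
            centroid_x=float((ccc + 0.5).mean() * grid.attrs["cell_size_m"]),
            centroid_y=float((crr + 0.5).mean() * grid.attrs["cell_size_m"]),
            weight=w_i, undercount=False,
            truth_pop=n_true, truth_density=d_i, truth_logdensity=z_i,
            truth_expected_logdensity=dbar_i, truth_footprint_area=A_i,
            truth_weight_outlier=outlier, truth_zero_footprint=False,
            truth_undercount=False, truth_random_round=bool(is_random_round),
            **cov_i,
        ))
    table = pd.DataFrame.from_records(records)

    # artifacts: undercounted enumeration; footprints not detected
    n = len(table)
    n_under = int(round(design.undercount_cluster_rate * n))
    n_zero = int(round(design.zero_footprint_rate * n))
    art = rng.permutation(n)
    under_idx = art[:n_under]
    zero_idx = art[n_under:n_under + n_zero]
    enumerated = table["truth_pop"].to_numpy().copy()
    if n_under:
        keep = rng.uniform(0.2, 0.5, size=n_under)
        enumerated[under_idx] = rng.binomial(enumerated[under_idx], keep)
        table.loc[under_idx, "undercount"] = True
        table.loc[under_idx, "truth_undercount"] = True
    if n_zero:
        table.loc[zero_idx, "footprint_area"] = 0.0
        table.loc[zero_idx, "truth_zero_footprint"] = True
    table["pop_enumerated"] = enumerated

    # household records (for nonresponse imputation)
    hid = 0
    for i, n_i in enumerate(enumerated):
        n_hh = max(1, int(round(n_i / design.mean_household_size)))
        sizes = rng.multinomial(int(n_i), np.full(n_hh, 1.0 / n_hh)).astype(float)
        miss = rng.random(n_hh) < design.nonresponse_rate
        if miss.all():
            miss[rng.integers(n_hh)] = False
        sizes[miss] = np.nan
        for s in sizes:
            hh_rows.append((i, hid, s))
            hid += 1
    households = pd.DataFrame(hh_rows, columns=["cluster_id", "household_id", "size"])

    # province-level age-sex individuals drawn Multinomial(N_p, pi_p);
    # individuals are spread over the province's clusters in proportion to
    # cluster size so that cluster-holdout validation is possible
    ind_rows = []
    pi = truth.pi
    prov_arr = table["province"].to_numpy()
    for p in range(int(grid.attrs["n_provinces"])):
        sel = prov_arr == p
        n_p = int(enumerated[sel].sum())
        if n_p == 0:
            continue
        cids = table.loc[sel, "cluster_id"].to_numpy()
        share = enumerated[sel].astype(float)
        share = share / share.sum() if share.sum() > 0 else np.full(len(cids), 1 / len(cids))
        counts = rng.multinomial(n_p, pi[p].to_numpy())
        for (sex, age_bin), cnt in zip(GROUP_LABELS, counts):
            if cnt == 0:
                continue
            k = AGE_BIN_LABELS.index(age_bin)
            lo = AGE_BIN_EDGES[k]
            hi = AGE_BIN_EDGES[k + 1]
            hi = 96 if np.isinf(hi) else hi
            ages = rng.integers(int(lo), int(hi), size=cnt)
            ind_rows.append(pd.DataFrame({
                "province": p, "sex": sex, "age": ages,
                "cluster_id": rng.choice(cids, size=cnt, p=share)}))
    individuals = (pd.concat(ind_rows, ignore_index=True) if ind_rows
                   else pd.DataFrame(columns=["province", "sex", "age",
                                              "cluster_id"]))

    return SurveyData(clusters=table, households=households,
                      individuals=individuals, design=design)
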