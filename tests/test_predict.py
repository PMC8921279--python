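"""Gridded posterior prediction: pooled precision, predictive moments,
age-sex splitting, polygon aggregation."""

import numpy as np
import pytest
import shapely
import xarray as xr

import gridpop as gp
from gridpop.mcmc import PosteriorDraws
from gridpop.model import ModelConfig


def constant_draws(alpha_val, beta_val, tau_val, T=2, P=1, L=1, K=1, S=200):
    """A PosteriorDraws whose parameters are constant across draws."""
    draws = {
        "alpha": np.full((1, S, T, L), alpha_val),
        "beta": np.full((1, S, K, T), beta_val),
        "tau_tp": np.full((1, S, T, P), tau_val),
    }
    return PosteriorDraws(draws=draws, config=ModelConfig(chains=1),
                          seed=0, covariate_names=("x0",))


def single_cell_grid(area_ha, ncell=1):
    settled = np.ones((1, ncell), dtype=bool)
    a = np.full((1, ncell), float(area_ha))
    zeros = np.zeros((1, ncell))
    return xr.Dataset(
        data_vars=dict(
            settled=(("row", "col"), settled),
            footprint_area=(("row", "col"), a),
            mean_area=(("row", "col"), zeros),
            proximity=(("row", "col"), zeros),
            focal_count=(("row", "col"), zeros),
            settlement_type=(("row", "col"), np.zeros((1, ncell), np.int8)),
            province=(("row", "col"), np.zeros((1, ncell), np.int16)),
            local_area=(("row", "col"), np.zeros((1, ncell), np.int16)),
        ),
        coords=dict(x=("col", (np.arange(ncell) + 0.5) * 100),
                    y=("row", np.array([50.0]))),
        attrs=dict(cell_size_m=100.0, cell_area_ha=1.0, n_provinces=1,
                   n_localareas=1, n_localareas_per_province=1),
    )


def unit_data(v=None, I=1):
    v = np.ones(I) if v is None else np.asarray(v, float)
    return gp.PreparedData(
        N=np.full(I, 10), A=np.ones(I), X=np.zeros((I, 1)),
        t=np.zeros(I, int), p=np.zeros(I, int), l=np.zeros(I, int),
        v=v, local_province=np.zeros(1, int), covariate_names=("x0",),
        n_provinces=1)


class TestPooledPrecision:
    def test_equal_weights_scale_by_inverse_sqrt(self):
        tau = np.full((3, 2, 1), 0.6)
        v = np.full(4, 0.25)
        out, _ = gp.pooled_precision(tau, v, np.zeros(4, int), np.zeros(4, int))
        np.testing.assert_allclose(out[:, 0, 0], 0.6 / np.sqrt(0.25))

    def test_single_cluster_returns_cluster_scale(self):
        tau = np.full((2, 2, 1), 0.5)
        v = np.array([0.3])
        out, _ = gp.pooled_precision(tau, v, np.zeros(1, int), np.zeros(1, int))
        np.testing.assert_allclose(out[:, 0, 0], 0.5 / np.sqrt(0.3))

    def test_matches_direct_summation_oracle(self, rng):
        tau = rng.uniform(0.2, 1.0, (5, 2, 3))
        I = 40
        t = rng.integers(0, 2, I)
        p = rng.integers(0, 3, I)
        v = rng.dirichlet(np.ones(I))
        out, _ = gp.pooled_precision(tau, v, t, p)
        for s in range(5):
            for tt in range(2):
                for pp in range(3):
                    m = (t == tt) & (p == pp)
                    if not m.any():
                        continue
                    tau_i = tau[s, tt, pp] / np.sqrt(v[m])
                    oracle = np.sum(tau_i * np.sqrt(v[m])) / np.sum(np.sqrt(v[m]))
                    np.testing.assert_allclose(out[s, tt, pp], oracle,
                                               atol=1e-12)

    def test_empty_stratum_falls_back_to_type_pooling(self):
        tau = np.full((2, 2, 2), 0.5)
        v = np.array([1.0, 1.0])
        t = np.array([0, 0])
        p = np.array([0, 0])
        out, log = gp.pooled_precision(tau, v, t, p)
        assert log["empty_strata"]
        assert np.isfinite(out).all()
        # stratum (0, 1) has no clusters: pooled over type 0
        np.testing.assert_allclose(out[:, 0, 1], out[:, 0, 0])


class TestPredictCells:
    def test_zero_footprint_cells_predict_exactly_zero(self, small_world, fitted):
        scaler = small_world["scaler"]
        pred = gp.predict_cells(fitted, small_world["grid"], scaler,
                                small_world["data"], n_draws=50, seed=1)
        a = small_world["grid"]["footprint_area"].values
        for stat in ("mean", "q025", "q975"):
            vals = pred.summary[stat].values
            assert (vals[a == 0] == 0).all()

    def test_interval_orders_cellwise(self, small_world, fitted):
        pred = gp.predict_cells(fitted, small_world["grid"],
                                small_world["scaler"], small_world["data"],
                                n_draws=50, seed=1)
        s = pred.summary
        assert (s["q025"].values <= s["mean"].values + 1e-9).all()
        assert (s["mean"].values <= s["q975"].values + 1e-9).all()

    def test_matches_lognormal_mean_oracle(self):
        """With constant parameters the cell mean approaches
        A * exp(dbar + tau_hat^2 / 2)."""
        alpha, tau, A = 3.0, 0.4, 2.0
        draws = constant_draws(alpha, 0.0, tau, S=40000)
        grid = single_cell_grid(A)
        scaler = gp.CovariateScaler(("mean_area", "proximity", "focal_count"),
                                    np.zeros(3), np.ones(3))
        draws.draws["beta"] = np.zeros((1, 40000, 3, 2))
        data = unit_data()           # v = 1 so tau_hat = tau
        pred = gp.predict_cells(draws, grid, scaler, data, n_draws=None,
                                seed=3)
        closed = A * np.exp(alpha + tau ** 2 / 2)
        d = pred.draws[0]
        mcse = d.std() / np.sqrt(len(d))
        assert abs(d.mean() - closed) < 3 * mcse

    def test_degenerate_scale_recovers_poisson_mean(self):
        alpha, A = 2.0, 1.5
        draws = constant_draws(alpha, 0.0, 1e-9, K=3, S=30000)
        grid = single_cell_grid(A)
        scaler = gp.CovariateScaler(("mean_area", "proximity", "focal_count"),
                                    np.zeros(3), np.ones(3))
        data = unit_data()
        pred = gp.predict_cells(draws, grid, scaler, data, n_draws=None, seed=4)
        closed = A * np.exp(alpha)
        d = pred.draws[0]
        assert abs(d.mean() - closed) < 3 * d.std() / np.sqrt(len(d))


class TestApplyAgesex:
    def _proportions(self, pi_vec, S):
        from gridpop.agesex import ProportionsPosterior
        import pandas as pd
        G = len(pi_vec)
        idx = pd.MultiIndex.from_tuples(
            [("all", f"g{j}") for j in range(G)], names=["sex", "age_bin"])
        return ProportionsPosterior(
            draws={0: np.tile(pi_vec, (S, 1))}, summary=None, group_index=idx)

    def _pred(self, small_world, fitted):
        return gp.predict_cells(fitted, small_world["grid"],
                                small_world["scaler"], small_world["data"],
                                n_draws=30, seed=5)

    def test_degenerate_proportions_assign_everything_to_first_group(
            self, small_world, fitted):
        pred = self._pred(small_world, fitted)
        S = pred.draws.shape[1]
        pi = np.zeros(4)
        pi[0] = 1.0
        # single-province view: all cells in province 0 for this check
        grid = small_world["grid"].copy(deep=True)
        grid["province"].values[:] = 0
        out = gp.apply_agesex(pred, self._proportions(pi, S), grid)
        np.testing.assert_allclose(out[("all", "g0")]["mean"].values,
                                   pred.summary["mean"].values)
        np.testing.assert_allclose(out[("all", "g1")]["mean"].values, 0.0)

    def test_uniform_proportions_split_evenly_and_sum_back(
            self, small_world, fitted):
        pred = self._pred(small_world, fitted)
        S = pred.draws.shape[1]
        G = 36
        pi = np.full(G, 1.0 / G)
        grid = small_world["grid"].copy(deep=True)
        grid["province"].values[:] = 0
        out = gp.apply_agesex(pred, self._proportions(pi, S), grid)
        total = sum(v["mean"].values for v in out.values())
        np.testing.assert_allclose(total, pred.summary["mean"].values,
                                   atol=1e-9)
        first = next(iter(out.values()))["mean"].values
        np.testing.assert_allclose(first, pred.summary["mean"].values / G,
                                   atol=1e-9)

    def test_missing_province_rejected(self, small_world, fitted):
        pred = self._pred(small_world, fitted)
        S = pred.draws.shape[1]
        with pytest.raises(ValueError, match="province"):
            gp.apply_agesex(pred, self._proportions(np.ones(4) / 4, S),
                            small_world["grid"])


@pytest.fixture(scope="module")
def pred(small_world, fitted):
    return gp.predict_cells(fitted, small_world["grid"],
                            small_world["scaler"], small_world["data"],
                            n_draws=40, seed=6)


class TestAggregate:
    def test_whole_grid_polygon_conserves_totals(self, small_world, pred):
        grid = small_world["grid"]
        big = shapely.box(0, 0, float(grid["x"].max() + 50),
                          float(grid["y"].max() + 50))
        out = gp.aggregate(pred, grid, {"all": big})
        per_draw = pred.draws.sum(axis=0)
        np.testing.assert_allclose(out.loc[0, "mean"], per_draw.mean())
        np.testing.assert_allclose(out.loc[0, "q025"],
                                   np.quantile(per_draw, 0.025))

    def test_partition_adds_to_grid_total(self, small_world, pred):
        grid = small_world["grid"]
        xmax = float(grid["x"].max() + 50)
        ymax = float(grid["y"].max() + 50)
        left = shapely.box(0, 0, xmax / 2, ymax)
        right = shapely.box(xmax / 2, 0, xmax, ymax)
        out = gp.aggregate(pred, grid, {"l": left, "r": right})
        np.testing.assert_allclose(out["mean"].sum(), pred.draws.sum(axis=0).mean())
        assert out["n_cells"].sum() == pred.draws.shape[0]

    def test_enlarging_polygon_never_decreases_mean(self, small_world, pred):
        grid = small_world["grid"]
        small = shapely.box(0, 0, 3000, 3000)
        large = shapely.box(0, 0, 6000, 6000)
        out = gp.aggregate(pred, grid, {"s": small, "l": large})
        assert out.loc[1, "mean"] >= out.loc[0, "mean"]

    def test_polygon_outside_grid_flagged_empty(self, small_world, pred):
        grid = small_world["grid"]
        out = gp.aggregate(pred, grid, {"far": shapely.box(1e6, 1e6, 2e6, 2e6)})
        assert bool(out.loc[0, "empty"]) and out.loc[0, "mean"] == 0

    def test_interval_matches_per_draw_bruteforce(self, small_world, pred):
        grid = small_world["grid"]
        poly = shapely.box(1000, 1000, 5000, 4000)
        out = gp.aggregate(pred, grid, {"p": poly})
        rr, cc = pred.cell_index
        xs = grid["x"].values[cc]
        ys = grid["y"].values[rr]
        inside = (xs >= 1000) & (xs <= 5000) & (ys >= 1000) & (ys <= 4000)
        sums = pred.draws[inside].sum(axis=0)
        np.testing.assert_allclose(out.loc[0, "q975"], np.quantile(sums, 0.975))
        np.testing.assert_allclose(out.loc[0, "median"], np.quantile(sums, 0.5))
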