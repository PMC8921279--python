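import numpy as np
import pytest

import gridpop as gp


@pytest.fixture(scope="session")
def small_world():
    """A compact two-province world with known truth and a random-sampling
    survey, shared across tests."""
    cfg = gp.WorldConfig(n_provinces=2, n_localareas_per_province=4,
                         grid_shape=(80, 80), settled_fraction=0.35, seed=11)
    grid = gp.generate_world(cfg)
    truth = gp.draw_truth(cfg)
    design = gp.SurveyDesign(mode="random", n_clusters=200,
                             undercount_cluster_rate=0.0,
                             zero_footprint_rate=0.0)
    sv = gp.simulate_survey(grid, truth, design, seed=5)
    prep, _ = gp.prepare_survey(sv.clusters, sv.households)
    scaler = gp.fit_scaler(grid, gp.COVARIATE_NAMES)
    data = gp.prepare_model_data(prep, scaler, truth.local_province,
                                 cfg.n_provinces)
    return dict(cfg=cfg, grid=grid, truth=truth, survey=sv, prep=prep,
                scaler=scaler, data=data)


@pytest.fixture(scope="session")
def fitted(small_world):
    """A posterior fit of the small world, shared by sampler, prediction and
    diagnostics tests."""
    mc = gp.ModelConfig(chains=3, iterations=2000, burn_in=800)
    draws = gp.sample_posterior(small_world["data"], mc, seed=7)
    return draws


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
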