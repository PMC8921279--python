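"""Validate the fitted model: cross-validation, residual metrics, spatial
autocorrelation.

Reproduces the goodness-of-fit table (bias, imprecision, inaccuracy, R2,
95% interval coverage; scaled variants) for in-sample and out-of-sample
predictions of cluster totals and densities, and tests residuals for
spatial structure."""

import numpy as np

import gridpop as gp

cfg = gp.WorldConfig(n_provinces=2, n_localareas_per_province=4,
                     grid_shape=(100, 100), settled_fraction=0.35, seed=1)
grid = gp.generate_world(cfg)
truth = gp.draw_truth(cfg)
survey = gp.simulate_survey(grid, truth,
                            gp.SurveyDesign(mode="random", n_clusters=300),
                            seed=2)
prep, _ = gp.prepare_survey(survey.clusters, survey.households)
scaler = gp.fit_scaler(grid, gp.COVARIATE_NAMES)
data = gp.prepare_model_data(prep, scaler, truth.local_province,
                             cfg.n_provinces)

config = gp.ModelConfig(chains=2, iterations=2000, burn_in=800)
draws = gp.sample_posterior(data, config, seed=3)

# in-sample posterior predictions
tot_in, dens_in = gp.posterior_predict_clusters(draws, data, data,
                                                n_draws=400, seed=4)
# out-of-sample via 10-fold cross-validation
cv = gp.crossvalidate(data, config, k=10, seed=5, n_draws_pred=400)

obs_tot = data.N.astype(float)
obs_dens = data.N / data.A
entries = {
    ("Population totals", "In-sample"): gp.residual_metrics(obs_tot, tot_in),
    ("Population totals", "Out-of-sample"):
        gp.residual_metrics(obs_tot, cv.totals_draws),
    ("Population densities", "In-sample"):
        gp.residual_metrics(obs_dens, dens_in),
    ("Population densities", "Out-of-sample"):
        gp.residual_metrics(obs_dens, cv.density_draws),
}
print(gp.metrics_table(entries).round(3).to_string(index=False))

resid = cv.totals_draws.mean(axis=1) - obs_tot
moran = gp.morans_i(resid, data.coords, seed=6)
print(f"\nMoran's I of out-of-sample residuals: {moran.I:+.4f} "
      f"(null expectation {moran.expected:+.4f}), "
      f"permutation p = {moran.p_perm:.3f}, normal p = {moran.p_norm:.3f}")
sv = gp.semivariogram(resid, data.coords, bins=6)
print("\nsemivariogram of residuals (flat when no spatial structure):")
print(sv.round(1).to_string(index=False))
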