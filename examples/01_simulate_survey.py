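"""Simulate a synthetic study region and a microcensus survey.

Builds a gridded world of ~100 m cells with building-footprint summaries,
draws ground-truth model parameters, and enumerates a population-weighted
cluster survey with the artifacts seen in real campaigns (weight outliers,
undercounted clusters, clusters whose footprints were never detected)."""

import gridpop as gp

cfg = gp.WorldConfig(n_provinces=2, n_localareas_per_province=4,
                     grid_shape=(100, 100), settled_fraction=0.35, seed=1)
grid = gp.generate_world(cfg)
truth = gp.draw_truth(cfg)
design = gp.SurveyDesign(mode="population_weighted", n_clusters=300)
survey = gp.simulate_survey(grid, truth, design, seed=2)

st = grid["settlement_type"].values
print(f"settled cells: {int(grid['settled'].sum())} "
      f"(urban {int((st == 1).sum())}, rural {int((st == 0).sum())})")
print(f"clusters enumerated: {len(survey.clusters)}")
print(f"households: {len(survey.households)} "
      f"({int(survey.households['size'].isna().sum())} nonresponses)")
print(f"people enumerated: {int(survey.clusters['pop_enumerated'].sum())}")
print(f"undercount-flagged clusters: {int(survey.clusters['undercount'].sum())}")
print(f"zero-footprint clusters: "
      f"{int((survey.clusters['footprint_area'] == 0).sum())}")
print("\ntrue log-density intercepts (rural/urban rows, one column per "
      "local area):")
print(truth.alpha.round(2))
# Each cluster is ~3 settled hectares; its population count N_i follows a
# Poisson around density x footprint area, so pop_enumerated/footprint_area
# scatters around exp(alpha) for its stratum.
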