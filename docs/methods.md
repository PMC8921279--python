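# Methods

## Model

`gridpop` estimates population bottom-up: a sample of fully enumerated
microcensus clusters is linked to building-footprint covariates, and the
fitted model predicts people per ~100 m cell everywhere footprints exist.
The observation model is

    N_i ~ Poisson(D_i A_i),      D_i ~ LogNormal(D̄_i, τ_{t,p}/√v_i),
    D̄_i = α_{t,p,l} + Σ_k β_{k,t} x_{k,i},

with footprint area A_i (ha) as exposure and density D_i in people per
footprint hectare. Intercepts are nested settlement type → province →
local area with normal/uniform hyperpriors; covariate effects are random
by settlement type with a shared mean ρ_k and scale ω_k, and a fixed
single-coefficient variant per covariate. Scale priors are half-normals
(normals truncated below at zero) and uniforms.

Two notational conventions are deliberate package choices, because the
precision/scale vocabulary for this model family is ambiguous across MCMC
systems:

* the second LogNormal argument is the **standard deviation on the log
  scale**; the weighted per-cluster term is τ_{t,p}/√v_i, so a larger
  model weight v_i means a smaller scale, i.e. more likelihood precision;
* `Normal(0, 1000)` is read as **variance** 1000 (sd ≈ 31.6), the common
  "precision 0.001" vague prior; `Uniform(0, 1000)` bounds are on the sd
  scale.

Latent densities D_i are explicit parameters (sampled, not marginalized),
which keeps the posterior-predictive machinery and the diagnostics simple.

### Weights

Model weights are v_i = w_i⁻¹/Σ w_i⁻¹, where w_i is the recorded sampling
weight of a population-weighted design (proportional to the noisy
population proxy that drove selection). Oversampled clusters therefore get
*small* v_i — low likelihood precision — which is the Horvitz–Thompson
direction: the precision-weighted conditional mean of a stratum intercept
is Σ v_i Z_i / Σ v_i, an inverse-propensity-weighted average. Weights are
truncated at the 90th percentile before use (outlier control); clusters
from a randomly sampled round have no weights and receive the mean
observed weight, so each round contributes in proportion to its cluster
count. "Proportionally impute" admits several readings; this rule is the
simplest consistent one and is isolated in `impute_missing_weights` so it
can be replaced.

### Prediction

Per-cluster precision needs a weight, which unsurveyed cells lack, so
prediction uses the pooled stratum scale

    τ̂_{t,p} = Σ_i τ_{t,p,i} √v_i / Σ_i √v_i     (τ_{t,p,i} = τ_{t,p}/√v_i),

which algebraically reduces to I_{t,p} τ_{t,p} / Σ √v_i; the code computes
the literal weighted average and the tests note the reduction. A stratum
with no training clusters falls back to pooling over its settlement type
(logged). Per cell and per posterior draw, D̂_j ~ LogNormal(D̄_j, τ̂) and
N_j ~ Poisson(D̂_j A_j); cells with zero footprint area are exactly zero.
Uncertainty is carried as **per-cell draws**, and polygon aggregation sums
within draws before taking quantiles — sums of cell quantiles would
misstate interval widths. Cells belong to a polygon by cell-center
containment (area-weighted splitting would be a straightforward
extension). Summaries default to the full set of retained draws; 10,000
posterior draws is the reference basis, thinned reproducibly when memory
matters. Per-cell means are left continuous (individual draws are integer
counts).

### Age–sex structure

Counts N_{g,p} in G = 36 groups (two sexes × 18 bins: [0,1), [1,5),
five-year bins to 80, 80+) follow Multinomial(N_p, π_p) with conjugate
prior Dirichlet(1/G, …, 1/G), so the posterior Dirichlet(1/G + N_{g,p}) is
sampled exactly — no MCMC. Proportions are modeled per province only:
holding them at sub-provincial level invites spurious estimates for the
smallest groups at realistic sample sizes. Cross-validation of the age–sex
model compares held-out aggregates against the **posterior predictive** of
an aggregate of that sample size (multinomial noise on top of π
uncertainty), matching how prediction intervals are assessed for totals.

## Sampler

Metropolis-within-Gibbs, exploiting the conditional structure:

* latent Z_i = log D_i: vectorized random-walk Metropolis, one proposal
  per cluster per sweep, per-cluster step sizes adapted toward 44%
  acceptance during burn-in only (Robbins-Monro, frozen afterwards);
* α, ξ, β, ρ: exact normal conjugate draws (β jointly per settlement type
  via Cholesky);
* all scale parameters (ν, τ, μ, σ, ω): univariate slice sampling
  (stepping-out + shrinkage), which handles the uniform upper bounds and
  the half-normal truncation normalizers without tuning.

Defaults: 3 chains, 10,000 iterations each including 1,000 burn-in, no
thinning (the burn-in/thinning split is a package choice; only the total
iteration budget and chain count have an external reference point).
Initialization is dispersed around data moments (log empirical densities
plus noise) so the Gelman-Rubin statistic is meaningful; the classic
(non-split) R̂ is the default, with a split variant available, and R̂ < 1.1
is read as convergence. Monitoring covers the α/β/τ hierarchies and the
derived τ̂; latent Z_i are optional (memory).

## Synthetic worlds

The generator emulates exactly the structure the model assumes, plus the
survey pathologies the preparation step must handle:

* smooth Gaussian fields thresholded into settled/unsettled cells and
  transformed into footprint summaries (area fraction, building size,
  nearest-neighbour distance ~ 50/√n m in a 1-ha cell, 2 km focal counts);
* settlement classification by connected components (8-neighbour):
  components with ≥ 40 ha footprint area and ≥ 13 buildings are urban;
* nested hierarchy truth drawn from the model's own generative form;
  default intercept levels put rural densities (e^5.7 ≈ 300 people per
  footprint ha) above urban (e^5.2 ≈ 180), with a strong shared negative
  effect of mean building area and type-specific proximity/focal-count
  effects;
* clusters grown as contiguous settled cells around a seed to ~3 settled
  hectares (a simplification of manual delineation); population-weighted
  sampling selects seeds ∝ footprint area × exp(predictor + residual),
  records that noisy proxy as w_i, and carries the *same* residual into
  the cluster's realized density — this makes selection informative beyond
  the covariates, which is precisely the bias the weighted precision must
  correct, and it is measurably corrected (the weighted fit beats the
  unweighted one on stratum-mean bias in ≥ 8/10 replicates);
* artifacts: heavy-tailed weight outliers (lognormal factor, testing the
  90th-percentile truncation), undercounted clusters (counts thinned to
  20–50%), clusters whose footprints are zeroed after counts are drawn,
  household nonresponse at rate 629/79,126. Default design sizes mirror
  the reference survey (926 clusters, 7 undercounted, 14 zero-footprint).
  The random/weighted round split is configurable (`random_fraction`);
  the default examples use a single-mode design.

What the synthetic worlds do **not** emulate: real settlement geometry and
imagery-derived footprint error (cloud/smoke obfuscation), spatially
correlated residuals, non-residential building mixes, and cluster
boundaries drawn by field teams. Passing recovery and coverage tests on
these worlds demonstrates the estimator is correct under its own
assumptions; it does not certify accuracy on real survey data, where
covariate aggregation error and footprint omissions (which inflate
observed densities) dominate the density-scale misfit.

## Validation

Residual metrics are computed on posterior-mean predictions: bias (mean
residual), imprecision (population sd of residuals, so bias² +
imprecision² = mean squared residual), inaccuracy (mean |residual|), R²
(squared Pearson correlation of observed vs posterior-mean predicted —
the conventional reading; the literal residual-correlation variant is
available via `r2_mode="residuals"`), and the percentage of observations
inside the central 95% prediction interval, each with a scaled companion
(residual/prediction). Out-of-sample behaviour uses seeded k-fold
cross-validation (default k = 10) with fold reassignment when a fold would
empty a stratum. Spatial structure is tested with Moran's I under
row-standardized inverse-distance weights — the weighting scheme is a
package choice, configurable — with a two-sided permutation p-value
(default 999 permutations) and the normal approximation reported
alongside, plus an empirical semivariogram with pair counts.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of the study
design: worlds of 80–120 cells on a side, 150–300 clusters, 1,500–3,000
sampler iterations with 2–3 chains — sizes at which the recovery,
convergence, coverage and weighted-bias properties are already stable and
a full run completes in minutes. The parameter-recovery experiment is run
as a 2-replicate smoke version in the suite; the 10-replicate version is
the nightly-scale variant of the same code path. Degenerate inputs follow
explicit contracts: empty weight vectors, all-missing clusters, zero grid
standard deviations, constant residuals and single-chain R̂ all raise;
zero-footprint clusters with positive counts have likelihood zero (the
log-joint returns -inf); ties in quantile-based intervals use linear
interpolation throughout (numpy's default).

## Known limitations

* Cluster covariates are aggregated from cell summaries
  (count-weighted means), so their distribution differs slightly from the
  cell-level distribution used for scaling; with strong covariate effects
  this can shift intercepts by a fraction of the residual scale.
* The weighted-precision correction assumes the recorded weight is
  proportional to the true selection propensity; weight noise and
  truncation leave residual bias.
* Moran's I permutation tests on cross-validated residuals can flag mild
  negative autocorrelation induced by partial pooling within local areas;
  this is a property of the residual construction, not of the field.
* No measurement-error model for counts or footprints; observed totals
  are taken as exact.
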