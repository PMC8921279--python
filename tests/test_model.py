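"""The hierarchical density model: linear predictor, weighted precision,
log-joint correctness against scipy's distributions, effect-mode decisions."""

import numpy as np
import pytest
from scipy import stats

import gridpop as gp
from gridpop.model import UNIFORM_UPPER, VAGUE_VAR, ModelConfig, ParameterSet


def make_data(rng, I=3, P=2, Lpp=2, K=2):
    L = P * Lpp
    local_province = np.repeat(np.arange(P), Lpp)
    l = rng.integers(0, L, I)
    return gp.PreparedData(
        N=rng.poisson(50, I),
        A=rng.uniform(0.5, 2.0, I),
        X=rng.normal(size=(I, K)),
        t=rng.integers(0, 2, I),
        p=local_province[l],
        l=l,
        v=rng.dirichlet(np.ones(I)),
        local_province=local_province,
        covariate_names=tuple(f"x{k}" for k in range(K)),
        n_provinces=P,
    )


def make_params(rng, data):
    T, P, L, K = 2, data.n_provinces, data.n_localareas, data.n_covariates
    nu_t = rng.uniform(0.5, 1.0, T)
    sigma_t = rng.uniform(0.5, 1.0, T)
    return ParameterSet(
        alpha=rng.normal(5, 0.5, (T, L)),
        xi_tp=rng.normal(5, 0.5, (T, P)),
        nu_tp=nu_t[:, None] * rng.uniform(0.2, 0.9, (T, P)),
        xi_t=rng.normal(5, 0.5, T),
        nu_t=nu_t,
        beta=rng.normal(0, 0.3, (K, T)),
        rho=rng.normal(0, 0.3, K),
        omega=rng.uniform(0.1, 0.5, K),
        tau_tp=rng.uniform(0.3, 0.8, (T, P)),
        mu_tp=rng.uniform(0.3, 0.8, (T, P)),
        sigma_tp=sigma_t[:, None] * rng.uniform(0.2, 0.9, (T, P)),
        mu_t=rng.normal(0.5, 0.1, T),
        sigma_t=sigma_t,
        Z=rng.normal(4, 0.5, data.n_clusters),
    )


class TestExpectedLogDensity:
    def test_zero_effects_return_intercept(self, rng):
        data = make_data(rng)
        params = make_params(rng, data)
        params.beta[:] = 0.0
        dbar = gp.expected_log_density(params, data)
        np.testing.assert_allclose(dbar, params.alpha[data.t, data.l])

    def test_single_unit_effect(self, rng):
        data = make_data(rng, I=1, K=3)
        params = make_params(rng, data)
        params.alpha[:] = 0.0
        params.beta[:] = 0.0
        params.beta[0, :] = 1.0
        data.X[0] = (2.0, 5.0, -3.0)
        np.testing.assert_allclose(gp.expected_log_density(params, data), [2.0])

    def test_matches_dot_product_oracle(self, rng):
        data = make_data(rng, I=20, K=4)
        params = make_params(rng, data)
        dbar = gp.expected_log_density(params, data)
        oracle = [params.alpha[data.t[i], data.l[i]]
                  + float(np.dot(params.beta[:, data.t[i]], data.X[i]))
                  for i in range(20)]
        np.testing.assert_allclose(dbar, oracle, atol=1e-12)


class TestEffectiveScale:
    def test_unit_weight_returns_tau(self):
        tau = np.array([[0.7]])
        s = gp.effective_scale(tau, np.array([1.0]), np.array([0]), np.array([0]))
        np.testing.assert_allclose(s, 0.7)

    def test_weight_four_halves_scale(self):
        tau = np.array([[0.8]])
        s = gp.effective_scale(tau, np.array([4.0]), np.array([0]), np.array([0]))
        np.testing.assert_allclose(s, 0.4)

    def test_scale_times_sqrt_weight_constant_within_stratum(self, rng):
        v = rng.uniform(0.1, 5, 10)
        tau = np.array([[0.6]])
        s = gp.effective_scale(tau, v, np.zeros(10, int), np.zeros(10, int))
        np.testing.assert_allclose(s * np.sqrt(v), 0.6)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            gp.effective_scale(np.array([[1.0]]), np.array([0.0]),
                               np.array([0]), np.array([0]))


def oracle_log_joint(params, data, modes):
    """Term-by-term recomputation with scipy.stats distributions."""
    lp = 0.0
    D = np.exp(params.Z)
    dbar = np.array([params.alpha[data.t[i], data.l[i]]
                     + params.beta[:, data.t[i]] @ data.X[i]
                     for i in range(data.n_clusters)])
    for i in range(data.n_clusters):
        lam = D[i] * data.A[i]
        lp += stats.poisson.logpmf(data.N[i], lam)
        s = params.tau_tp[data.t[i], data.p[i]] / np.sqrt(data.v[i])
        lp += stats.lognorm.logpdf(D[i], s=s, scale=np.exp(dbar[i]))
    T, P = params.xi_tp.shape
    for t in range(T):
        for l in range(data.n_localareas):
            p = data.local_province[l]
            lp += stats.norm.logpdf(params.alpha[t, l], params.xi_tp[t, p],
                                    params.nu_tp[t, p])
        for p in range(P):
            lp += stats.norm.logpdf(params.xi_tp[t, p], params.xi_t[t],
                                    params.nu_t[t])
            lp += stats.uniform.logpdf(params.nu_tp[t, p], 0, params.nu_t[t])
            a = -params.mu_tp[t, p] / params.sigma_tp[t, p]
            lp += stats.truncnorm.logpdf(params.tau_tp[t, p], a, np.inf,
                                         loc=params.mu_tp[t, p],
                                         scale=params.sigma_tp[t, p])
            a = -params.mu_t[t] / params.sigma_t[t]
            lp += stats.truncnorm.logpdf(params.mu_tp[t, p], a, np.inf,
                                         loc=params.mu_t[t],
                                         scale=params.sigma_t[t])
            lp += stats.uniform.logpdf(params.sigma_tp[t, p], 0,
                                       params.sigma_t[t])
        lp += stats.norm.logpdf(params.xi_t[t], 0, np.sqrt(VAGUE_VAR))
        lp += stats.uniform.logpdf(params.nu_t[t], 0, UNIFORM_UPPER)
        lp += stats.norm.logpdf(params.mu_t[t], 0, np.sqrt(VAGUE_VAR))
        lp += stats.uniform.logpdf(params.sigma_t[t], 0, UNIFORM_UPPER)
    for k, mode in enumerate(modes):
        if mode == "random":
            for t in range(T):
                lp += stats.norm.logpdf(params.beta[k, t], params.rho[k],
                                        params.omega[k])
            lp += stats.norm.logpdf(params.rho[k], 0, np.sqrt(VAGUE_VAR))
            lp += stats.uniform.logpdf(params.omega[k], 0, UNIFORM_UPPER)
        else:
            lp += stats.norm.logpdf(params.beta[k, 0], 0, np.sqrt(VAGUE_VAR))
    return float(lp)


class TestLogJoint:
    def test_matches_scipy_oracle(self, rng):
        for trial in range(5):
            data = make_data(rng)
            params = make_params(rng, data)
            modes = ("random", "fixed")
            params.beta[1, 1] = params.beta[1, 0]
            cfg = ModelConfig(effect_mode=modes)
            ours = gp.log_joint(params, data, cfg)
            oracle = oracle_log_joint(params, data, modes)
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_zero_area_zero_count_allowed(self, rng):
        data = make_data(rng, I=3)
        data.A[0] = 0.0
        data.N[0] = 0
        params = make_params(rng, data)
        assert np.isfinite(gp.log_joint(params, data))

    def test_zero_area_positive_count_impossible(self, rng):
        data = make_data(rng, I=3)
        data.A[0] = 0.0
        data.N[0] = 5
        params = make_params(rng, data)
        assert gp.log_joint(params, data) == -np.inf

    def test_support_violations_give_minus_inf(self, rng):
        data = make_data(rng)
        params = make_params(rng, data)
        base = gp.log_joint(params, data)
        assert np.isfinite(base)
        bad = params.copy()
        bad.nu_tp[0, 0] = bad.nu_t[0] * 2    # above the uniform bound
        assert gp.log_joint(bad, data) == -np.inf
        bad = params.copy()
        bad.tau_tp[0, 0] = -0.1
        assert gp.log_joint(bad, data) == -np.inf

    def test_extreme_latents_diverge(self, rng):
        data = make_data(rng)
        params = make_params(rng, data)
        base = gp.log_joint(params, data)
        for z in (-40.0, 40.0):
            worse = params.copy()
            worse.Z[:] = z
            assert gp.log_joint(worse, data) < base

    def test_equal_weights_drop_out_of_relative_comparisons(self, rng):
        """With all v_i equal, the weighted likelihood differs from the
        unweighted one only by a constant: log-joint differences across
        latent states coincide once tau absorbs the common factor."""
        data_w = make_data(rng, I=6)
        I = data_w.n_clusters
        v_eq = np.full(I, 1.0 / I)
        data_w = gp.PreparedData(**{**data_w.__dict__, "v": v_eq})
        data_u = gp.PreparedData(**{**data_w.__dict__, "v": np.ones(I)})
        params1 = make_params(rng, data_w)
        params2 = params1.copy()
        params2.Z = params1.Z + rng.normal(0, 0.2, I)
        # unweighted model at the rescaled tau' = tau / sqrt(v)
        p1u, p2u = params1.copy(), params2.copy()
        p1u.tau_tp = params1.tau_tp / np.sqrt(1.0 / I)
        p2u.tau_tp = p1u.tau_tp.copy()
        dw = gp.log_joint(params1, data_w) - gp.log_joint(params2, data_w)
        du = gp.log_joint(p1u, data_u) - gp.log_joint(p2u, data_u)
        np.testing.assert_allclose(dw, du, atol=1e-8)


class TestDecideEffectMode:
    def test_identical_draws_become_fixed(self, rng):
        d = rng.normal(size=(500, 2, 1))
        draws = np.concatenate([d, d], axis=2)
        rep = gp.decide_effect_mode(draws.reshape(500, 2, 2))
        assert rep["modes"] == ("fixed", "fixed")

    def test_disjoint_intervals_stay_random(self, rng):
        draws = np.empty((500, 1, 2))
        draws[:, 0, 0] = rng.uniform(-1.0, -0.5, 500)
        draws[:, 0, 1] = rng.uniform(0.5, 1.0, 500)
        rep = gp.decide_effect_mode(draws)
        assert rep["modes"] == ("random",)

    def test_planted_equal_effects_usually_fixed(self, rng):
        """When both settlement types share the same true effect, the
        interval criterion picks 'fixed' in at least 90% of replicates."""
        hits = 0
        for _ in range(40):
            draws = rng.normal(0.3, 0.1, size=(400, 1, 2))
            rep = gp.decide_effect_mode(draws)
            hits += rep["modes"][0] == "fixed"
        assert hits >= 36

    def test_missing_draws_rejected(self):
        with pytest.raises(ValueError):
            gp.decide_effect_mode(np.empty((1, 2, 2)))
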