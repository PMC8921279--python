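"""Posterior sampling for the hierarchical density model.

The sampler is a Metropolis-within-Gibbs scheme tailored to the model's
conditional structure: latent log-densities Z_i move by vectorized adaptive
random-walk Metropolis (independent across clusters given the parameters);
location parameters (alpha, xi, beta, rho) have normal conditionals and are
drawn exactly; scale parameters (nu, tau, mu, sigma, omega) are updated by
univariate slice sampling, which respects the uniform upper bounds and
half-normal truncations without tuning. Multiple chains with dispersed,
data-informed starts support the Gelman-Rubin convergence diagnostic
(values below 1.1 read as convergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import truncnorm

from .model import (
    N_TYPES,
    UNIFORM_UPPER,
    VAGUE_VAR,
    ModelConfig,
    ParameterSet,
    PreparedData,
    expected_log_density,
)

__all__ = ["PosteriorDraws", "sample_posterior", "gelman_rubin"]


@dataclass
class PosteriorDraws:
    """MCMC samples per parameter, indexed (chain, draw, *shape)."""

    draws: dict[str, np.ndarray]
    config: ModelConfig
    seed: int
    covariate_names: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Chains concatenated: (chains*draws, *shape)."""
        a = self.draws[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def scalars(self) -> dict[str, np.ndarray]:
        """Flatten to named scalar chains: label -> (chains, draws)."""
        out = {}
        for name, a in self.draws.items():
            if a.ndim == 2:
                out[name] = a
            else:
                flat = a.reshape(a.shape[0], a.shape[1], -1)
                shape = a.shape[2:]
                for j in range(flat.shape[2]):
                    idx = np.unravel_index(j, shape)
                    label = name + "[" + ",".join(map(str, idx)) + "]"
                    out[label] = flat[:, :, j]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (parameter, chain, iteration, value) table."""
        rows = []
        for label, a in self.scalars().items():
            C, S = a.shape
            rows.append(pd.DataFrame({
                "parameter": label,
                "chain": np.repeat(np.arange(C), S),
                "iteration": np.tile(np.arange(S), C),
                "value": a.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


def gelman_rubin(draws, split: bool = False) -> pd.Series:
    """Potential scale reduction factor per scalar parameter.

    Accepts a PosteriorDraws, a dict of (chains, draws) arrays, or a single
    (chains, draws) array. The default is the classic between/within-chain
    formula; ``split=True`` halves each chain first, which additionally
    flags within-chain drift. Constant chains return 1.0 (no between-chain
    disagreement to detect).
    """
    if isinstance(draws, PosteriorDraws):
        chains = draws.scalars()
    elif isinstance(draws, dict):
        chains = draws
    else:
        chains = {"x": np.asarray(draws)}
    out = {}
    for label, a in chains.items():
        a = np.asarray(a, dtype=float)
        if a.ndim != 2 or a.shape[0] < 2:
            raise ValueError("need a (chains >= 2, draws) array per parameter")
        if a.shape[1] < 10:
            raise ValueError("need at least 10 draws per chain")
        if split:
            half = a.shape[1] // 2
            a = np.concatenate([a[:, :half], a[:, half:2 * half]], axis=0)
        m, n = a.shape
        W = a.var(axis=1, ddof=1).mean()
        B_over_n = a.mean(axis=1).var(ddof=1)
        if W == 0:
            out[label] = 1.0
            continue
        var_plus = (n - 1) / n * W + B_over_n
        out[label] = float(np.sqrt(var_plus / W))
    return pd.Series(out, name="rhat")


# ---------------------------------------------------------------------------
# slice sampler (Neal 2003: stepping out + shrinkage), bounded support


def _slice_sample(x0: float, logf, rng, lower: float = 0.0,
                  upper: float = np.inf, w: float = 1.0,
                  max_steps: int = 50) -> float:
    y = logf(x0) - rng.exponential()
    u = rng.random()
    left = x0 - w * u
    right = left + w
    left = max(left, lower)
    right = min(right, upper)
    steps = max_steps
    while left > lower and steps > 0 and logf(left) > y:
        left = max(left - w, lower)
        steps -= 1
    steps = max_steps
    while right < upper and steps > 0 and logf(right) > y:
        right = min(right + w, upper)
        steps -= 1
    for _ in range(200):
        x1 = left + rng.random() * (right - left)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _draw_halfnormal(loc, sd, rng):
    a = (0.0 - loc) / sd
    return float(truncnorm.rvs(a, np.inf, loc=loc, scale=sd, random_state=rng))


# ---------------------------------------------------------------------------
# the Gibbs sweep


class _Sampler:
    def __init__(self, data: PreparedData, config: ModelConfig,
                 fixed: dict | None = None):
        self.data = data
        self.config = config
        self.fixed = fixed or {}
        self.T = N_TYPES
        self.P = data.n_provinces
        self.L = data.n_localareas
        self.K = data.n_covariates
        self.modes = config.modes(self.K)
        self.random_k = [k for k in range(self.K) if self.modes[k] == "random"]
        self.fixed_k = [k for k in range(self.K) if self.modes[k] == "fixed"]

        d = data
        self.g_tl = d.t * self.L + d.l
        self.g_tp = d.t * self.P + d.p
        self.n_tp = np.bincount(self.g_tp, minlength=self.T * self.P).reshape(self.T, self.P)
        self.sqrt_v = np.sqrt(d.v)
        self.sum_sqrt_v_tp = np.bincount(self.g_tp, weights=self.sqrt_v,
                                         minlength=self.T * self.P).reshape(self.T, self.P)
        # province membership of local areas, for the xi/nu updates
        self.prov_of_l = d.local_province
        self.Lpp = np.bincount(self.prov_of_l, minlength=self.P)  # areas per province

    # -- initialization ----------------------------------------------------

    def init_state(self, rng) -> tuple[ParameterSet, np.ndarray]:
        d = self.data
        T, P, L, K = self.T, self.P, self.L, self.K
        Z0 = np.log((d.N + 0.5) / np.maximum(d.A, 1e-6)) + rng.normal(0, 0.2, d.n_clusters)
        grand = float(Z0.mean())
        sum_tl = np.bincount(self.g_tl, weights=Z0, minlength=T * L).reshape(T, L)
        n_tl = np.bincount(self.g_tl, minlength=T * L).reshape(T, L)
        alpha0 = np.where(n_tl > 0, sum_tl / np.maximum(n_tl, 1), grand)
        alpha0 = alpha0 + rng.normal(0, 0.3, (T, L))
        beta0 = rng.normal(0, 0.2, (K, T))
        for k in self.fixed_k:
            beta0[k, :] = beta0[k, 0]
        resid = Z0 - alpha0[d.t, d.l] - np.einsum("ik,ki->i", d.X, beta0[:, d.t])
        # residual sd on the weighted scale: s_i = tau/sqrt(v_i)
        sw = np.bincount(self.g_tp, weights=d.v * resid ** 2,
                         minlength=T * P).reshape(T, P)
        tau0 = np.sqrt(sw / np.maximum(self.n_tp, 1))
        tau0 = np.where(self.n_tp > 0, tau0, np.nanmean(tau0[self.n_tp > 0]))
        tau0 = np.maximum(tau0, 1e-3) * np.exp(rng.normal(0, 0.2, (T, P)))

        xi_tp0 = np.zeros((T, P))
        for t in range(T):
            for p in range(P):
                sel = self.prov_of_l == p
                xi_tp0[t, p] = alpha0[t, sel].mean()
        xi_tp0 += rng.normal(0, 0.2, (T, P))
        nu_tp0 = np.full((T, P), max(0.2, float(alpha0.std()))) * np.exp(rng.normal(0, 0.2, (T, P)))
        xi_t0 = xi_tp0.mean(axis=1) + rng.normal(0, 0.2, T)
        nu_t0 = np.maximum(nu_tp0.max(axis=1) * 1.5, 0.3)
        rho0 = beta0.mean(axis=1) + rng.normal(0, 0.1, K)
        omega0 = np.full(K, 0.3) * np.exp(rng.normal(0, 0.2, K))
        mu_tp0 = np.maximum(tau0 * np.exp(rng.normal(0, 0.1, (T, P))), 1e-3)
        sigma_tp0 = np.maximum(0.5 * mu_tp0, 1e-3)
        mu_t0 = mu_tp0.mean(axis=1)
        sigma_t0 = np.maximum(sigma_tp0.max(axis=1) * 1.5, 0.2)

        params = ParameterSet(alpha=alpha0, xi_tp=xi_tp0, nu_tp=nu_tp0,
                              xi_t=xi_t0, nu_t=nu_t0, beta=beta0, rho=rho0,
                              omega=omega0, tau_tp=tau0, mu_tp=mu_tp0,
                              sigma_tp=sigma_tp0, mu_t=mu_t0, sigma_t=sigma_t0,
                              Z=Z0)
        for name, value in self.fixed.items():
            setattr(params, name, np.array(value, dtype=float))
        step = np.full(d.n_clusters, 0.5)
        return params, step

    # -- helpers -----------------------------------------------------------

    def _scales(self, params) -> np.ndarray:
        return params.tau_tp[self.data.t, self.data.p] / self.sqrt_v

    # -- block updates -----------------------------------------------------

    def update_Z(self, params, rng, step, adapt: bool, it: int):
        d = self.data
        Z = params.Z
        dbar = expected_log_density(params, d)
        s2 = self._scales(params) ** 2
        prop = Z + step * rng.standard_normal(d.n_clusters)

        def logp(z):
            pois = np.where(d.A > 0, d.N * z - d.A * np.exp(z), 0.0)
            return pois - 0.5 * (z - dbar) ** 2 / s2

        log_acc = logp(prop) - logp(Z)
        acc = np.log(rng.random(d.n_clusters)) < log_acc
        Z[acc] = prop[acc]
        if adapt:
            rate = 1.0 / np.sqrt(1 + it)
            step *= np.exp(rate * (acc.astype(float) - 0.44))
            np.clip(step, 1e-3, 10.0, out=step)

    def update_alpha(self, params, rng):
        d = self.data
        T, L = self.T, self.L
        r = params.Z - np.einsum("ik,ki->i", d.X, params.beta[:, d.t])
        w = 1.0 / self._scales(params) ** 2
        sum_w = np.bincount(self.g_tl, weights=w, minlength=T * L).reshape(T, L)
        sum_wr = np.bincount(self.g_tl, weights=w * r, minlength=T * L).reshape(T, L)
        prior_mean = params.xi_tp[:, self.prov_of_l]
        prior_prec = 1.0 / params.nu_tp[:, self.prov_of_l] ** 2
        post_prec = sum_w + prior_prec
        post_mean = (sum_wr + prior_mean * prior_prec) / post_prec
        params.alpha = post_mean + rng.standard_normal((T, L)) / np.sqrt(post_prec)

    def update_beta(self, params, rng):
        d = self.data
        w = 1.0 / self._scales(params) ** 2
        alpha_i = params.alpha[d.t, d.l]
        R, F = self.random_k, self.fixed_k
        if R:
            for t in range(self.T):
                sel = d.t == t
                contrib_f = (d.X[:, F] @ params.beta[F, 0]) if F else 0.0
                if not sel.any():
                    params.beta[R, t] = params.rho[R] + params.omega[R] \
                        * rng.standard_normal(len(R))
                    continue
                Xr = d.X[np.ix_(sel, R)]
                y = params.Z[sel] - alpha_i[sel] - (contrib_f[sel] if F else 0.0)
                ww = w[sel]
                prec = Xr.T @ (ww[:, None] * Xr) + np.diag(1.0 / params.omega[R] ** 2)
                b = Xr.T @ (ww * y) + params.rho[R] / params.omega[R] ** 2
                cf = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, b)
                z = rng.standard_normal(len(R))
                params.beta[R, t] = mean + np.linalg.solve(cf.T, z)
        if F:
            contrib_r = np.einsum("ik,ki->i", d.X[:, R], params.beta[np.ix_(R, d.t)]) if R else 0.0
            y = params.Z - alpha_i - contrib_r
            Xf = d.X[:, F]
            prec = Xf.T @ (w[:, None] * Xf) + np.eye(len(F)) / VAGUE_VAR
            b = Xf.T @ (w * y)
            cf = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, b)
            z = rng.standard_normal(len(F))
            draw = mean + np.linalg.solve(cf.T, z)
            for t in range(self.T):
                params.beta[F, t] = draw

    def update_effect_hypers(self, params, rng):
        for k in self.random_k:
            post_prec = self.T / params.omega[k] ** 2 + 1.0 / VAGUE_VAR
            post_mean = params.beta[k].sum() / params.omega[k] ** 2 / post_prec
            params.rho[k] = post_mean + rng.standard_normal() / np.sqrt(post_prec)
            ss = float(np.sum((params.beta[k] - params.rho[k]) ** 2))
            T = self.T

            def logf(om, ss=ss, T=T):
                return -T * np.log(om) - ss / (2 * om ** 2)

            params.omega[k] = _slice_sample(params.omega[k], logf, rng,
                                            lower=1e-6, upper=UNIFORM_UPPER,
                                            w=max(0.3, params.omega[k]))

    def update_intercept_hypers(self, params, rng):
        T, P = self.T, self.P
        for t in range(T):
            for p in range(P):
                sel = self.prov_of_l == p
                a = params.alpha[t, sel]
                n = len(a)
                nu2 = params.nu_tp[t, p] ** 2
                post_prec = n / nu2 + 1.0 / params.nu_t[t] ** 2
                post_mean = (a.sum() / nu2 + params.xi_t[t] / params.nu_t[t] ** 2) / post_prec
                params.xi_tp[t, p] = post_mean + rng.standard_normal() / np.sqrt(post_prec)
                ss = float(np.sum((a - params.xi_tp[t, p]) ** 2))

                def logf(nu, ss=ss, n=n):
                    return -n * np.log(nu) - ss / (2 * nu ** 2)

                params.nu_tp[t, p] = _slice_sample(
                    params.nu_tp[t, p], logf, rng, lower=1e-6,
                    upper=params.nu_t[t], w=max(0.2, params.nu_tp[t, p]))
            # type level
            nu_t2 = params.nu_t[t] ** 2
            post_prec = P / nu_t2 + 1.0 / VAGUE_VAR
            post_mean = params.xi_tp[t].sum() / nu_t2 / post_prec
            params.xi_t[t] = post_mean + rng.standard_normal() / np.sqrt(post_prec)
            ss = float(np.sum((params.xi_tp[t] - params.xi_t[t]) ** 2))
            lower = max(float(params.nu_tp[t].max()), 1e-6)

            def logf_t(nu, ss=ss, P=P):
                return -2 * P * np.log(nu) - ss / (2 * nu ** 2)

            params.nu_t[t] = _slice_sample(params.nu_t[t], logf_t, rng,
                                           lower=lower, upper=UNIFORM_UPPER,
                                           w=max(0.3, params.nu_t[t]))

    def update_tau(self, params, rng):
        d = self.data
        dbar = expected_log_density(params, d)
        ssw = np.bincount(self.g_tp, weights=d.v * (params.Z - dbar) ** 2,
                          minlength=self.T * self.P).reshape(self.T, self.P)
        for t in range(self.T):
            for p in range(self.P):
                n = int(self.n_tp[t, p])
                mu, sig = params.mu_tp[t, p], params.sigma_tp[t, p]
                if n == 0:
                    params.tau_tp[t, p] = _draw_halfnormal(mu, sig, rng)
                    continue
                ss = float(ssw[t, p])

                def logf(tau, ss=ss, n=n, mu=mu, sig=sig):
                    return (-n * np.log(tau) - ss / (2 * tau ** 2)
                            - (tau - mu) ** 2 / (2 * sig ** 2))

                params.tau_tp[t, p] = _slice_sample(
                    params.tau_tp[t, p], logf, rng, lower=1e-8,
                    w=max(0.1, 0.5 * params.tau_tp[t, p]))

    def update_tau_hypers(self, params, rng):
        T, P = self.T, self.P
        for t in range(T):
            for p in range(P):
                tau, sig = params.tau_tp[t, p], params.sigma_tp[t, p]
                mu_t, sig_t = params.mu_t[t], params.sigma_t[t]

                def logf_mu(mu, tau=tau, sig=sig, mu_t=mu_t, sig_t=sig_t):
                    return (-(tau - mu) ** 2 / (2 * sig ** 2) - log_ndtr(mu / sig)
                            - (mu - mu_t) ** 2 / (2 * sig_t ** 2))

                params.mu_tp[t, p] = _slice_sample(
                    params.mu_tp[t, p], logf_mu, rng, lower=1e-8,
                    w=max(0.1, 0.5 * params.mu_tp[t, p]))
                mu = params.mu_tp[t, p]

                def logf_sig(s, tau=tau, mu=mu):
                    return (-np.log(s) - (tau - mu) ** 2 / (2 * s ** 2)
                            - log_ndtr(mu / s))

                params.sigma_tp[t, p] = _slice_sample(
                    params.sigma_tp[t, p], logf_sig, rng, lower=1e-8,
                    upper=params.sigma_t[t], w=max(0.1, 0.5 * params.sigma_tp[t, p]))
            mus, sig_t = params.mu_tp[t], params.sigma_t[t]

            def logf_mu_t(m, mus=mus, sig_t=sig_t, P=P):
                return (-np.sum((mus - m) ** 2) / (2 * sig_t ** 2)
                        - P * log_ndtr(m / sig_t) - m ** 2 / (2 * VAGUE_VAR))

            params.mu_t[t] = _slice_sample(params.mu_t[t], logf_mu_t, rng,
                                           lower=-np.inf, upper=np.inf,
                                           w=max(0.2, 0.5 * abs(params.mu_t[t])))
            mu_t = params.mu_t[t]
            lower = max(float(params.sigma_tp[t].max()), 1e-8)

            def logf_sig_t(s, mus=mus, mu_t=mu_t, P=P):
                return (-np.sum((mus - mu_t) ** 2) / (2 * s ** 2)
                        - 2 * P * np.log(s) - P * log_ndtr(mu_t / s))

            params.sigma_t[t] = _slice_sample(params.sigma_t[t], logf_sig_t,
                                              rng, lower=lower,
                                              upper=UNIFORM_UPPER,
                                              w=max(0.2, params.sigma_t[t]))

    def sweep(self, params, rng, step, adapt, it):
        fx = self.fixed
        if "Z" not in fx:
            self.update_Z(params, rng, step, adapt, it)
        if "alpha" not in fx:
            self.update_alpha(params, rng)
        if "beta" not in fx:
            self.update_beta(params, rng)
        if "rho" not in fx and "omega" not in fx and self.random_k:
            self.update_effect_hypers(params, rng)
        if not {"xi_tp", "nu_tp", "xi_t", "nu_t"} & fx.keys():
            self.update_intercept_hypers(params, rng)
        if "tau_tp" not in fx:
            self.update_tau(params, rng)
        if not {"mu_tp", "sigma_tp", "mu_t", "sigma_t"} & fx.keys():
            self.update_tau_hypers(params, rng)

    def tau_hat_factor(self) -> np.ndarray:
        """Stratum factor turning tau_tp draws into the pooled prediction
        scale: tau_hat = factor * tau_tp (empty strata fall back to the
        settlement-type level)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = self.n_tp / self.sum_sqrt_v_tp
        n_t = self.n_tp.sum(axis=1)
        s_t = self.sum_sqrt_v_tp.sum(axis=1)
        parent = np.where(s_t > 0, n_t / np.maximum(s_t, 1e-300), 1.0)
        factor = np.where(self.n_tp > 0, factor, parent[:, None])
        return factor


_MONITORED = ("alpha", "beta", "tau_tp", "xi_tp", "nu_tp", "xi_t", "nu_t",
              "rho", "omega", "mu_tp", "sigma_tp", "mu_t", "sigma_t")


def sample_posterior(data: PreparedData, config: ModelConfig | None = None,
                     seed: int | None = None, fixed: dict | None = None,
                     monitor_latent: bool = False) -> PosteriorDraws:
    """Draw from the posterior of the density model.

    Runs ``config.chains`` chains of ``config.iterations`` sweeps, discards
    ``config.burn_in``, thins by ``config.thin`` and returns the kept draws.
    ``fixed`` clamps named parameter blocks to given values (used in tests
    to reduce the sampler to conjugate subproblems). Deterministic given
    ``seed``.
    """
    config = config or ModelConfig()
    if seed is None:
        seed = config.seed
    sampler = _Sampler(data, config, fixed)
    kept = (config.iterations - config.burn_in) // config.thin
    if kept < 1:
        raise ValueError("no draws kept; increase iterations")

    store: dict[str, np.ndarray] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(config.chains)
    for c in range(config.chains):
        rng = np.random.default_rng(child_seeds[c])
        params, step = sampler.init_state(rng)
        # bounded retries for a finite starting density
        from .model import log_joint
        for _ in range(20):
            if np.isfinite(log_joint(params, data, config)):
                break
            params, step = sampler.init_state(rng)
        else:
            raise RuntimeError("could not find a finite-density initial state")
        s = 0
        for it in range(config.iterations):
            sampler.sweep(params, rng, step, adapt=it < config.burn_in, it=it)
            if (it >= config.burn_in and s < kept
                    and (it - config.burn_in) % config.thin == 0):
                if not store:
                    names = list(_MONITORED) + (["Z"] if monitor_latent else [])
                    for name in names:
                        arr = getattr(params, name)
                        store[name] = np.empty((config.chains, kept) + arr.shape)
                for name in store:
                    if name != "tau_hat":
                        store[name][c, s] = getattr(params, name)
                s += 1
    factor = sampler.tau_hat_factor()
    store["tau_hat"] = store["tau_tp"] * factor[None, None, :, :]
    return PosteriorDraws(draws=store, config=config, seed=seed,
                          covariate_names=data.covariate_names)
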