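"""Weighted-precision hierarchical Poisson-lognormal density model.

The observation model for a microcensus cluster i is

    N_i ~ Poisson(D_i A_i)
    D_i ~ LogNormal(Dbar_i, tau_{t,p} / sqrt(v_i))
    Dbar_i = alpha_{t,p,l} + sum_k beta_{k,t} x_{k,i}

where N_i is the enumerated population, A_i the building-footprint area (ha),
D_i the latent density (people per footprint ha), v_i the normalized model
weight, and the second LogNormal argument the standard deviation on the log
scale. Dividing the log-scale sd by sqrt(v_i) scales each cluster's
likelihood precision by its model weight, which de-biases estimation under
population-weighted (preferential) cluster sampling.

Intercepts are nested settlement type -> province -> local area; covariate
effects are random by settlement type, collapsible to fixed effects when the
posteriors agree across types. Scale hyperpriors are half-normals and
uniforms; location hyperpriors are vague normals (variance 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr

__all__ = [
    "PreparedData",
    "ModelConfig",
    "ParameterSet",
    "prepare_model_data",
    "expected_log_density",
    "effective_scale",
    "log_joint",
    "decide_effect_mode",
]

VAGUE_VAR = 1000.0          # Normal(0, 1000): variance 1000, sd ~= 31.6
UNIFORM_UPPER = 1000.0      # Uniform(0, 1000) on the sd scale

N_TYPES = 2                 # rural (0), urban (1)


@dataclass(frozen=True)
class PreparedData:
    """Model-ready cluster observations.

    Arrays indexed by cluster: counts N (people), exposure A (footprint ha),
    scaled covariates X (I x K), settlement type t, province p, local area l,
    and normalized model weights v (sum to one).
    """

    N: np.ndarray
    A: np.ndarray
    X: np.ndarray
    t: np.ndarray
    p: np.ndarray
    l: np.ndarray
    v: np.ndarray
    local_province: np.ndarray      # (L,) province of each local area
    covariate_names: tuple[str, ...]
    n_provinces: int
    coords: np.ndarray | None = None   # (I, 2) cluster centroids, for diagnostics

    def __post_init__(self) -> None:
        I = len(self.N)
        for name in ("A", "X", "t", "p", "l", "v"):
            if len(getattr(self, name)) != I:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.N < 0) or np.any(self.A < 0):
            raise ValueError("counts and areas must be nonnegative")
        if np.any(self.v <= 0):
            raise ValueError("model weights must be positive")
        if np.any(self.local_province[self.l] != self.p):
            raise ValueError("local areas must nest in their provinces")

    @property
    def n_clusters(self) -> int:
        return len(self.N)

    @property
    def n_localareas(self) -> int:
        return len(self.local_province)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray, renormalize: bool = True) -> "PreparedData":
        """Row subset (e.g. a cross-validation fold), re-normalizing v."""
        v = self.v[idx]
        if renormalize:
            v = v / v.sum()
        return replace(self, N=self.N[idx], A=self.A[idx], X=self.X[idx],
                       t=self.t[idx], p=self.p[idx], l=self.l[idx], v=v,
                       coords=None if self.coords is None else self.coords[idx])


def prepare_model_data(table: pd.DataFrame, scaler, local_province: np.ndarray,
                       n_provinces: int,
                       covariate_names: tuple[str, ...] | None = None) -> PreparedData:
    """Build PreparedData from a prepared cluster table and a grid-level
    covariate scaler (the same constants used for prediction cells)."""
    names = tuple(covariate_names or scaler.names)
    X = scaler.transform(table[list(names)])
    coords = None
    if {"centroid_x", "centroid_y"}.issubset(table.columns):
        coords = table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    return PreparedData(
        N=table["pop_observed"].to_numpy(dtype=np.int64),
        A=table["footprint_area"].to_numpy(dtype=float),
        X=X,
        t=table["settlement_type"].to_numpy(dtype=np.int64),
        p=table["province"].to_numpy(dtype=np.int64),
        l=table["local_area"].to_numpy(dtype=np.int64),
        v=table["v"].to_numpy(dtype=float),
        local_province=np.asarray(local_province, dtype=np.int64),
        covariate_names=names,
        n_provinces=int(n_provinces),
        coords=coords,
    )


@dataclass(frozen=True)
class ModelConfig:
    """Sampler and structure configuration.

    ``iterations`` is the total per chain including burn-in; the kept draws
    number ``(iterations - burn_in) // thin``. ``effect_mode`` holds
    "random" (by settlement type) or "fixed" per covariate.
    """

    effect_mode: tuple[str, ...] | None = None
    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.effect_mode is not None:
            bad = set(self.effect_mode) - {"random", "fixed"}
            if bad:
                raise ValueError(f"unknown effect modes: {bad}")

    def modes(self, K: int) -> tuple[str, ...]:
        if self.effect_mode is None:
            return ("random",) * K
        if len(self.effect_mode) != K:
            raise ValueError("effect_mode length must match covariate count")
        return self.effect_mode


@dataclass
class ParameterSet:
    """All model unknowns. beta is stored (K, T) even for fixed-mode
    covariates (the two columns are then identical)."""

    alpha: np.ndarray       # (T, L)
    xi_tp: np.ndarray       # (T, P)
    nu_tp: np.ndarray       # (T, P)
    xi_t: np.ndarray        # (T,)
    nu_t: np.ndarray        # (T,)
    beta: np.ndarray        # (K, T)
    rho: np.ndarray         # (K,)
    omega: np.ndarray       # (K,)
    tau_tp: np.ndarray      # (T, P)
    mu_tp: np.ndarray       # (T, P)
    sigma_tp: np.ndarray    # (T, P)
    mu_t: np.ndarray        # (T,)
    sigma_t: np.ndarray     # (T,)
    Z: np.ndarray           # (I,) latent log densities

    def copy(self) -> "ParameterSet":
        return ParameterSet(**{k: np.array(getattr(self, k), copy=True)
                               for k in self.__dataclass_fields__})


def expected_log_density(params: ParameterSet, data: PreparedData) -> np.ndarray:
    """Dbar_i = alpha_{t,p,l} + sum_k beta_{k,t} x_{k,i} for every cluster."""
    if np.any(data.l >= params.alpha.shape[1]) or np.any(data.t >= params.alpha.shape[0]):
        raise ValueError("cluster hierarchy labels outside parameter index space")
    return (params.alpha[data.t, data.l]
            + np.einsum("ik,ki->i", data.X, params.beta[:, data.t]))


def effective_scale(tau_tp: np.ndarray, v: np.ndarray, t: np.ndarray,
                    p: np.ndarray) -> np.ndarray:
    """Per-cluster log-scale sd tau_{t,p} / sqrt(v_i): larger model weight
    means smaller scale, i.e. higher likelihood precision."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("model weights must be positive")
    tau = np.asarray(tau_tp, dtype=float)[t, p]
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    return tau / np.sqrt(v)


def _norm_logpdf(x, loc, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - loc) / sd) ** 2


def _halfnorm_logpdf(x, loc, sd):
    """Normal(loc, sd) truncated below at zero."""
    return _norm_logpdf(x, loc, sd) - log_ndtr(loc / sd)


def log_joint(params: ParameterSet, data: PreparedData,
              config: ModelConfig | None = None) -> float:
    """Log joint density of parameters, latent densities and data.

    Sums the Poisson log-likelihood of N_i given D_i A_i, the lognormal
    density of D_i given (Dbar_i, tau_{t,p}/sqrt(v_i)), and all hierarchical
    prior terms. Returns -inf outside the support.
    """
    config = config or ModelConfig()
    K = data.n_covariates
    modes = config.modes(K)

    scales = np.concatenate([params.nu_tp.ravel(), params.nu_t, params.omega,
                             params.tau_tp.ravel(), params.mu_tp.ravel(),
                             params.sigma_tp.ravel(), params.sigma_t])
    if np.any(scales <= 0):
        return -np.inf
    if np.any(params.nu_tp > params.nu_t[:, None]) or np.any(params.nu_t > UNIFORM_UPPER):
        return -np.inf
    if np.any(params.sigma_tp > params.sigma_t[:, None]) or np.any(params.sigma_t > UNIFORM_UPPER):
        return -np.inf
    if np.any(params.omega > UNIFORM_UPPER):
        return -np.inf
    if np.any(params.mu_tp <= 0):
        return -np.inf

    Z = params.Z
    D = np.exp(Z)
    lam = D * data.A
    with np.errstate(divide="ignore", invalid="ignore"):
        pois = np.where(lam > 0,
                        data.N * np.log(np.where(lam > 0, lam, 1.0)) - lam
                        - gammaln(data.N + 1.0),
                        np.where(data.N == 0, 0.0, -np.inf))
    if np.any(np.isneginf(pois)):
        return -np.inf
    lp = float(pois.sum())

    dbar = expected_log_density(params, data)
    s = effective_scale(params.tau_tp, data.v, data.t, data.p)
    # lognormal density of D_i (= normal in Z minus the Jacobian term Z)
    lp += float(np.sum(_norm_logpdf(Z, dbar, s) - Z))

    # intercept hierarchy
    lp += float(np.sum(_norm_logpdf(params.alpha,
                                    params.xi_tp[:, data.local_province],
                                    params.nu_tp[:, data.local_province])))
    lp += float(np.sum(_norm_logpdf(params.xi_tp, params.xi_t[:, None],
                                    params.nu_t[:, None])))
    lp += float(np.sum(-np.log(params.nu_t[:, None]) * np.ones_like(params.nu_tp)))
    lp += float(np.sum(_norm_logpdf(params.xi_t, 0.0, np.sqrt(VAGUE_VAR))))
    lp += float(np.sum(-np.log(UNIFORM_UPPER) * np.ones_like(params.nu_t)))

    # covariate effects
    for k in range(K):
        if modes[k] == "random":
            lp += float(np.sum(_norm_logpdf(params.beta[k], params.rho[k],
                                            params.omega[k])))
            lp += float(_norm_logpdf(params.rho[k], 0.0, np.sqrt(VAGUE_VAR)))
            lp += -np.log(UNIFORM_UPPER)
        else:
            lp += float(_norm_logpdf(params.beta[k, 0], 0.0, np.sqrt(VAGUE_VAR)))

    # density-scale hierarchy
    lp += float(np.sum(_halfnorm_logpdf(params.tau_tp, params.mu_tp, params.sigma_tp)))
    lp += float(np.sum(_halfnorm_logpdf(params.mu_tp, params.mu_t[:, None],
                                        params.sigma_t[:, None])))
    lp += float(np.sum(-np.log(params.sigma_t[:, None]) * np.ones_like(params.sigma_tp)))
    lp += float(np.sum(_norm_logpdf(params.mu_t, 0.0, np.sqrt(VAGUE_VAR))))
    lp += float(np.sum(-np.log(UNIFORM_UPPER) * np.ones_like(params.sigma_t)))
    return lp


def decide_effect_mode(beta_draws: np.ndarray, level: float = 0.95,
                       covariate_names: tuple[str, ...] | None = None) -> dict:
    """Decide per covariate whether the by-type random effects collapse to a
    fixed effect.

    ``beta_draws`` has shape (draws, K, T). A covariate becomes "fixed" when
    the central credible interval of beta_{k,urban} - beta_{k,rural} at the
    given level contains zero; otherwise it stays "random".
    """
    draws = np.asarray(beta_draws, dtype=float)
    if draws.ndim != 3 or draws.shape[2] != N_TYPES:
        raise ValueError("beta_draws must have shape (draws, K, T=2)")
    if draws.shape[0] < 2:
        raise ValueError("need posterior draws to compare effects")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    out = {"modes": [], "intervals": []}
    K = draws.shape[1]
    names = covariate_names or tuple(f"x{k}" for k in range(K))
    for k in range(K):
        diff = draws[:, k, 1] - draws[:, k, 0]
        lo, hi = np.quantile(diff, [lo_q, hi_q])
        mode = "fixed" if lo <= 0.0 <= hi else "random"
        out["modes"].append(mode)
        out["intervals"].append((float(lo), float(hi)))
    out["modes"] = tuple(out["modes"])
    out["by_covariate"] = {n: m for n, m in zip(names, out["modes"])}
    return out
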