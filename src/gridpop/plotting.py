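"""Standard figures: population pyramids, intercept posteriors,
observed-versus-predicted scatter with credible intervals."""

from __future__ import annotations

import numpy as np

from .survey import AGE_BIN_LABELS, SEXES


def plot_pyramid(proportions, province, ax=None):
    """Population pyramid of posterior mean age-sex proportions with 95%
    credible intervals for one province."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    s = proportions.summary
    s = s[s["province"] == province]
    y = np.arange(len(AGE_BIN_LABELS))
    for sex, sign, color in (("female", -1, "tab:purple"), ("male", 1, "tab:orange")):
        sub = s[s["sex"] == sex].set_index("age_bin").reindex(AGE_BIN_LABELS)
        ax.barh(y, sign * sub["mean"], color=color, alpha=0.6, label=sex)
        ax.errorbar(sign * sub["mean"], y,
                    xerr=[sub["mean"] - sub["q025"], sub["q975"] - sub["mean"]],
                    fmt="none", ecolor="black", elinewidth=0.8)
    ax.set_yticks(y, AGE_BIN_LABELS)
    ax.set_xlabel("proportion of population")
    ax.set_title(f"province {province}")
    ax.legend()
    return ax


def plot_obs_vs_pred(observed, pred_draws, settlement_type=None, ax=None,
                     label=""):
    """Observed values against posterior-mean predictions with 95% intervals
    and the 1:1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pred = pred_draws.mean(axis=1)
    lo = np.quantile(pred_draws, 0.025, axis=1)
    hi = np.quantile(pred_draws, 0.975, axis=1)
    colors = np.array(["#20b2aa", "#e75480"])
    c = colors[np.asarray(settlement_type)] if settlement_type is not None else "#20b2aa"
    ax.errorbar(observed, pred, yerr=[pred - lo, hi - pred], fmt="none",
                ecolor="lightgray", elinewidth=0.6, zorder=1)
    ax.scatter(observed, pred, c=c, s=12, zorder=2)
    lim = [0, max(np.max(observed), hi.max()) * 1.05]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel(f"observed {label}")
    ax.set_ylabel(f"predicted {label}")
    return ax


def plot_intercepts(draws, local_province, ax=None):
    """Posterior distributions of the settlement-type/province intercept
    means (xi_tp), mirroring the by-type intercept comparison."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    xi = draws.stacked("xi_tp")      # (M, T, P)
    T, P = xi.shape[1], xi.shape[2]
    colors = ("#20b2aa", "#e75480")
    names = ("rural", "urban")
    for p in range(P):
        for t in range(T):
            vals = xi[:, t, p]
            y = p + (t - 0.5) * 0.2
            ax.errorbar(vals.mean(), y,
                        xerr=[[vals.mean() - np.quantile(vals, 0.025)],
                              [np.quantile(vals, 0.975) - vals.mean()]],
                        fmt="o", color=colors[t],
                        label=names[t] if p == 0 else None)
    ax.set_yticks(range(P), [f"province {p}" for p in range(P)])
    ax.set_xlabel("intercept (log people / footprint ha)")
    ax.legend()
    return ax
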