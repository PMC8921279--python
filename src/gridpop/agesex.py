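"""Dirichlet-multinomial model of province-level age-sex structure.

Counts N_{g,p} of people in the G = 36 age-sex groups of a province follow
Multinomial(N_p, pi_p); the uninformative conjugate prior on the proportion
vector is Dirichlet(1/G, ..., 1/G), so the posterior is
Dirichlet(1/G + N_{g,p}) and can be sampled exactly — no MCMC needed.
Proportions are estimated per province only: sub-provincial sample sizes
would make the smallest groups spurious.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import AgeSexTable

__all__ = ["ProportionsPosterior", "fit_agesex", "closed_form_summary"]


@dataclass
class ProportionsPosterior:
    """Posterior draws and summaries of age-sex proportions.

    ``draws`` maps province -> (n_draws, G) array on the G-simplex;
    ``summary`` is a DataFrame with (province, sex, age_bin) rows and
    mean / q025 / q975 columns.
    """

    draws: dict
    summary: pd.DataFrame
    group_index: pd.MultiIndex

    def mean(self, province) -> np.ndarray:
        return self.draws[province].mean(axis=0)


def _check_counts(table: AgeSexTable) -> pd.DataFrame:
    counts = table.counts
    if (counts.sum(axis=0) <= 0).any():
        bad = [p for p, tot in table.totals.items() if tot <= 0]
        raise ValueError(f"provinces with zero total population: {bad}")
    return counts


def fit_agesex(table: AgeSexTable, n_draws: int = 10_000,
               seed: int | None = None) -> ProportionsPosterior:
    """Exact conjugate posterior of age-sex proportions per province.

    Draws ``n_draws`` samples from Dirichlet(1/G + counts) for each province
    and summarizes posterior means with central 95% credible intervals.
    """
    counts = _check_counts(table)
    G = counts.shape[0]
    rng = np.random.default_rng(seed)
    draws = {}
    rows = []
    for p in counts.columns:
        conc = counts[p].to_numpy(dtype=float) + 1.0 / G
        d = rng.dirichlet(conc, size=n_draws)
        draws[p] = d
        q = np.quantile(d, [0.025, 0.975], axis=0)
        for j, (sex, age_bin) in enumerate(counts.index):
            rows.append((p, sex, age_bin, d[:, j].mean(), q[0, j], q[1, j]))
    summary = pd.DataFrame(rows, columns=["province", "sex", "age_bin",
                                          "mean", "q025", "q975"])
    return ProportionsPosterior(draws=draws, summary=summary,
                                group_index=counts.index)


def closed_form_summary(table: AgeSexTable) -> pd.DataFrame:
    """Analytic Dirichlet posterior moments, the oracle for ``fit_agesex``.

    With concentration a_g = N_g + 1/G and a0 = N_p + 1, the posterior mean
    is a_g / a0 and the variance a_g (a0 - a_g) / (a0^2 (a0 + 1)).
    """
    counts = _check_counts(table)
    G = counts.shape[0]
    rows = []
    for p in counts.columns:
        a = counts[p].to_numpy(dtype=float) + 1.0 / G
        a0 = a.sum()
        mean = a / a0
        var = a * (a0 - a) / (a0 ** 2 * (a0 + 1.0))
        for j, (sex, age_bin) in enumerate(counts.index):
            rows.append((p, sex, age_bin, mean[j], var[j]))
    return pd.DataFrame(rows, columns=["province", "sex", "age_bin",
                                       "mean", "var"])
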