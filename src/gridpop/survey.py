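"""Survey preparation: from raw microcensus tables to model-ready observations.

A microcensus cluster is a small, fully enumerated survey area (~3 settled
hectares) providing one observation of a population count N_i together with
the building-footprint area A_i it sits on. This module performs household
nonresponse imputation, discards clusters with spurious attributes
(undercounted enumeration, no detected footprints), truncates sampling-weight
outliers at the 90th percentile, imputes weights for randomly sampled
clusters, converts sampling weights w_i into normalized model weights
v_i = w_i^-1 / sum(w_i^-1), and aggregates individual records into the
36 age-sex groups used by the compositional model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BIN_EDGES",
    "AGE_BIN_LABELS",
    "SEXES",
    "GROUP_LABELS",
    "AgeSexTable",
    "impute_nonresponse",
    "filter_clusters",
    "truncate_weights",
    "impute_missing_weights",
    "normalize_weights",
    "aggregate_agesex",
    "constrain_cluster_extent",
    "prepare_survey",
]

#: Standardized age bins: under 1, 1-4, then 5-year bins to 80, then 80+.
AGE_BIN_EDGES: tuple[float, ...] = (0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45,
                                    50, 55, 60, 65, 70, 75, 80, np.inf)
AGE_BIN_LABELS: tuple[str, ...] = tuple(
    ["<1", "1-4"]
    + [f"{lo}-{hi - 1}" for lo, hi in zip(AGE_BIN_EDGES[2:-2], AGE_BIN_EDGES[3:-1])]
    + ["80+"]
)
SEXES: tuple[str, str] = ("female", "male")
#: 36 age-sex groups, ordered sex-major.
GROUP_LABELS: tuple[tuple[str, str], ...] = tuple(
    (s, a) for s in SEXES for a in AGE_BIN_LABELS
)


@dataclass
class AgeSexTable:
    """Counts of people per age-sex group g and province p.

    ``counts`` is a (G x P) DataFrame indexed by a (sex, age) MultiIndex with
    one column per province; totals per province are derived.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("age-sex counts must be nonnegative")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_groups(self) -> int:
        return self.counts.shape[0]

    @property
    def provinces(self) -> list:
        return list(self.counts.columns)


def impute_nonresponse(households: pd.DataFrame,
                       cluster_col: str = "cluster_id",
                       size_col: str = "size") -> pd.Series:
    """Impute nonresponding households with the mean of responding households
    in the same cluster and return completed cluster population totals.

    Raises if any cluster has no responding household (nothing to impute
    from).
    """
    totals = {}
    for cid, grp in households.groupby(cluster_col, sort=True):
        sizes = grp[size_col].to_numpy(dtype=float)
        observed = sizes[~np.isnan(sizes)]
        n_missing = int(np.isnan(sizes).sum())
        if observed.size == 0:
            raise ValueError(f"cluster {cid!r} has no responding household")
        totals[cid] = float(observed.sum() + n_missing * observed.mean())
    return pd.Series(totals, name="pop_observed")


def filter_clusters(table: pd.DataFrame,
                    undercount_col: str = "undercount",
                    area_col: str = "footprint_area") -> tuple[pd.DataFrame, dict]:
    """Drop clusters flagged as undercounted and clusters with zero footprint
    area; report both counts (a cluster matching both rules is discarded
    once)."""
    under = table[undercount_col].fillna(False).astype(bool)
    zero_fp = table[area_col].to_numpy(dtype=float) <= 0
    discard = under.to_numpy() | zero_fp
    report = {
        "n_input": int(len(table)),
        "n_undercount": int(under.sum()),
        "n_zero_footprint": int(zero_fp.sum()),
        "n_discarded": int(discard.sum()),
        "n_retained": int((~discard).sum()),
    }
    return table.loc[~discard].copy(), report


def truncate_weights(weights, percentile: float = 90.0) -> np.ndarray:
    """Cap sampling weights at the given percentile of their distribution
    (linear-interpolation quantile). Values at or below the percentile are
    unchanged; NaN (missing) entries pass through untouched."""
    w = np.asarray(weights, dtype=float)
    obs = w[~np.isnan(w)]
    if obs.size == 0:
        raise ValueError("empty weight vector")
    if np.any(obs <= 0):
        raise ValueError("weights must be positive")
    cap = np.percentile(obs, percentile)
    out = w.copy()
    out[~np.isnan(w)] = np.minimum(obs, cap)
    return out


def impute_missing_weights(weights) -> np.ndarray:
    """Fill missing sampling weights (randomly sampled clusters) with the
    mean observed weight, so each survey round contributes in proportion to
    its cluster count."""
    w = np.asarray(weights, dtype=float)
    missing = np.isnan(w)
    obs = w[~missing]
    if obs.size == 0:
        raise ValueError("all weights missing; nothing to impute from")
    out = w.copy()
    out[missing] = obs.mean()
    return out


def normalize_weights(weights) -> np.ndarray:
    """Model weights v_i = w_i^-1 / sum_i w_i^-1 (sum to one)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and complete")
    inv = 1.0 / w
    return inv / inv.sum()


def aggregate_agesex(individuals: pd.DataFrame,
                     province_col: str = "province",
                     sex_col: str = "sex",
                     age_col: str = "age") -> AgeSexTable:
    """Aggregate individual records into the 36 age-sex groups per province."""
    ages = individuals[age_col].to_numpy(dtype=float)
    if np.any(ages < 0) or np.any(~np.isfinite(ages)):
        raise ValueError("ages must be finite and nonnegative")
    sexes = individuals[sex_col]
    if not sexes.isin(SEXES).all():
        raise ValueError(f"sex must be one of {SEXES}")
    binned = pd.cut(ages, bins=list(AGE_BIN_EDGES), labels=AGE_BIN_LABELS,
                    right=False, include_lowest=True)
    df = pd.DataFrame({
        "province": individuals[province_col].to_numpy(),
        "sex": sexes.to_numpy(),
        "age_bin": binned,
    })
    counts = (
        df.groupby(["sex", "age_bin", "province"], observed=False)
        .size().unstack("province", fill_value=0)
    )
    idx = pd.MultiIndex.from_tuples(GROUP_LABELS, names=["sex", "age_bin"])
    counts = counts.reindex(idx, fill_value=0)
    return AgeSexTable(counts)


def constrain_cluster_extent(household_points, footprints,
                             radius_m: float = 50.0) -> list[int]:
    """Indices of footprints within ``radius_m`` of any surveyed household.

    The boundary is closed: a footprint at exactly the radius is included.
    Distances are polygon-to-point. Footprints farther than the radius from
    every household were plausibly not surveyed (accessibility constraints)
    and are excluded from the cluster's footprint area and covariates.
    """
    pts = list(household_points)
    if len(pts) == 0:
        raise ValueError("empty household set")
    kept = []
    for i, fp in enumerate(footprints):
        if any(fp.distance(p) <= radius_m for p in pts):
            kept.append(i)
    return kept


@dataclass
class PrepReport:
    """Record of the decisions taken while preparing a survey."""

    filter: dict = field(default_factory=dict)
    weight_cap: float = float("nan")
    n_weights_truncated: int = 0
    n_weights_imputed: int = 0

    def to_dict(self) -> dict:
        return {
            "filter": dict(self.filter),
            "weight_cap": self.weight_cap,
            "n_weights_truncated": self.n_weights_truncated,
            "n_weights_imputed": self.n_weights_imputed,
        }


def prepare_survey(clusters: pd.DataFrame, households: pd.DataFrame | None = None,
                   weight_percentile: float = 90.0) -> tuple[pd.DataFrame, PrepReport]:
    """Full preparation pipeline on a raw cluster table.

    Imputes household nonresponse into cluster totals (when households are
    given), applies the discard rules, truncates weights at the 90th
    percentile, imputes missing weights, and attaches normalized model
    weights ``v``. Returns the model-ready table and a report.
    """
    table = clusters.copy()
    if households is not None:
        totals = impute_nonresponse(households)
        table["pop_observed"] = totals.reindex(table["cluster_id"]).to_numpy()
    if "pop_observed" not in table.columns:
        raise ValueError("no pop_observed column and no household records given")
    table["pop_observed"] = np.rint(table["pop_observed"]).astype(int)

    report = PrepReport()
    table, report.filter = filter_clusters(table)

    w = table["weight"].to_numpy(dtype=float)
    obs = w[~np.isnan(w)]
    if obs.size:
        cap = np.percentile(obs, weight_percentile)
        report.weight_cap = float(cap)
        report.n_weights_truncated = int((obs > cap).sum())
        w = truncate_weights(w, weight_percentile)
        report.n_weights_imputed = int(np.isnan(w).sum())
        w = impute_missing_weights(w)
    else:
        # fully random design: no weight information, equal weights
        report.n_weights_imputed = len(w)
        w = np.ones_like(w)
    table["weight"] = w
    table["v"] = normalize_weights(w)
    return table.reset_index(drop=True), report
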