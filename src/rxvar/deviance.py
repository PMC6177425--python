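"""Drug-county deviance: population-standardized signed deviance residuals.

For each drug d, national bin weights w_{d,b} = n_{d,b} / sum_b' n_{d,b'}
standardize every county to the national bin distribution. The county's
weighted observed events y_{d,c} = sum_b w_{d,b} y_{d,b,c} are compared with
the weighted model expectation yhat_{d,c} = sum_b w_{d,b} n_{d,b,c} p_{d,b}
via the signed binomial deviance residual

    G_{d,c} = sign(y - yhat) * [ y*log(y/yhat)
              + (n - y)*log((n - y)/(n - yhat)) ]^(1/2)

with the x*log(x) -> 0 limit at the boundaries. Note the bracket carries no
factor of 2: the statistic is the signed root of an un-doubled binomial
deviance, implemented exactly as defined (see docs/methods.md for why this
differs from the textbook residual by sqrt(2)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "compute_weights",
    "standardize_and_expect",
    "deviance_residual",
    "build_deviance_matrix",
]

log = logging.getLogger(__name__)


def compute_weights(national_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-drug national bin weights, the fraction of the drug's national
    risk set falling in each bin. Drugs with an empty national risk set are
    excluded with a warning."""
    nc = national_counts.copy()
    totals = nc.groupby("drug_id")["n"].transform("sum")
    empty = nc.loc[totals == 0, "drug_id"].unique()
    if len(empty):
        log.warning("excluding %d drugs with empty national risk sets: %s",
                    len(empty), list(empty[:5]))
        nc = nc[totals > 0]
        totals = totals[totals > 0]
    nc = nc.assign(w=nc["n"] / totals)
    return nc[["drug_id", "bin_id", "w"]]


def standardize_and_expect(
    county_counts: pd.DataFrame,
    weights: pd.DataFrame,
    p_hat: pd.DataFrame,
) -> pd.DataFrame:
    """Weighted county at-risk / observed / expected totals per (drug, county).

    ``county_counts``: (drug_id, bin_id, county_id, n, y);
    ``p_hat``: (drug_id, bin_id, p) fitted national probabilities. A bin
    observed in a county but missing a fitted probability is a hard error —
    no silent imputation.
    """
    df = county_counts.merge(weights, on=["drug_id", "bin_id"], how="inner")
    df = df.merge(p_hat, on=["drug_id", "bin_id"], how="left", validate="many_to_one")
    if df["p"].isna().any():
        bad = df.loc[df["p"].isna(), ["drug_id", "bin_id"]].drop_duplicates().head()
        raise ValueError(f"missing fitted probability for observed bins:\n{bad}")
    df["n_w"] = df["w"] * df["n"]
    df["y_w"] = df["w"] * df["y"]
    df["yhat_w"] = df["w"] * df["n"] * df["p"]
    out = (
        df.groupby(["drug_id", "county_id"], sort=True)[["n_w", "y_w", "yhat_w"]]
        .sum()
        .reset_index()
    )
    return out


def deviance_residual(y, yhat, n):
    """Signed root binomial deviance (un-doubled) of observed vs expected.

    Vectorized over arrays. Boundary conventions: x*log(x/e) terms are 0 at
    x = 0; ``yhat`` is clamped to [eps, n - eps] with eps = 1e-8 * n; a
    bracket made slightly negative by floating error near y = yhat is
    truncated to 0.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(y < -1e-12) or np.any(y - n > 1e-9):
        raise ValueError("require 0 <= y <= n")
    eps = 1e-8 * n
    yh = np.clip(yhat, eps, n - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / yh), 0.0)
        ny = n - y
        t2 = np.where(ny > 0, ny * np.log(np.where(ny > 0, ny, 1.0) / (n - yh)), 0.0)
    bracket = np.maximum(t1 + t2, 0.0)
    return np.sign(y - yh) * np.sqrt(bracket)


def build_deviance_matrix(
    summaries: pd.DataFrame,
    min_person_years: float = 0.0,
    with_log_ratio: bool = False,
):
    """Assemble the counties x drugs matrix of G_{d,c}.

    Counties whose total weighted person-years fall below
    ``min_person_years`` are excluded (logged). Returns a DataFrame indexed
    by county_id with drug_id columns; with ``with_log_ratio`` also returns
    the companion log(y/yhat) matrix under the same boundary conventions.
    """
    s = summaries.copy()
    county_tot = s.groupby("county_id")["n_w"].sum()
    keep = county_tot[county_tot >= min_person_years].index
    dropped = county_tot.index.difference(keep)
    if len(dropped):
        log.info("excluding %d counties below the %.1f person-year floor",
                 len(dropped), min_person_years)
    s = s[s["county_id"].isin(keep)]
    s["G"] = deviance_residual(s["y_w"], s["yhat_w"], s["n_w"])
    G = s.pivot(index="county_id", columns="drug_id", values="G").sort_index()
    G = G[sorted(G.columns)]
    if not with_log_ratio:
        return G
    eps = 1e-8 * s["n_w"]
    yh = np.clip(s["yhat_w"], eps, s["n_w"] - eps)
    yy = np.maximum(s["y_w"], eps)
    s["log_ratio"] = np.log(yy / yh)
    L = s.pivot(index="county_id", columns="drug_id", values="log_ratio").sort_index()
    return G, L[sorted(L.columns)]


def aggregate_summaries(summaries: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Re-aggregate county summaries to coarser units (e.g. states).

    ``mapping`` maps county_id -> unit id. Weighted counts are additive, so
    the unit-level deviance is the same statistic computed at unit
    granularity (per-state deviance vectors for the rank-sum analyses).
    """
    s = summaries.copy()
    unit = s["county_id"].map(mapping)
    if unit.isna().any():
        missing = s.loc[unit.isna(), "county_id"].unique()
        raise KeyError(f"counties missing from mapping: {list(missing[:5])}")
    s["county_id"] = unit
    return (
        s.groupby(["drug_id", "county_id"], sort=True)[["n_w", "y_w", "yhat_w"]]
        .sum()
        .reset_index()
    )


def write_deviance_csv(G: pd.DataFrame, path) -> None:
    """deviance.csv: drug ids in the header, county ids in the first column."""
    G.to_csv(path, index_label="county_id", float_format="%.17g")


def read_deviance_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str}, float_precision="round_trip")
    return df.set_index("county_id")
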