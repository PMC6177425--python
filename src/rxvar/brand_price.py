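"""Regional brand-versus-generic preference from the deviance matrix.

A joint linear model of drug-county deviance on therapeutic-class fixed
effects plus a per-geographic-unit x brand-indicator interaction yields one
brand-preference coefficient per county (or state): positive means the unit
uses brand-only drugs more than its class-level baseline predicts. The
preference is then modelled from county demographics (elastic net), and
class-level correlations between price/brand status and component
association are computed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import elastic_net_predict, spearman_test
from .synthetic_claims import catalog_class_map

__all__ = [
    "brand_preference_fit",
    "brand_demographic_model",
    "class_price_correlation",
]


def brand_preference_fit(
    deviance_matrix: pd.DataFrame,
    catalog: pd.DataFrame,
    grouping: str = "county",
    state_of: pd.Series | None = None,
    unit_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-unit brand coefficients from one joint OLS.

    Rows are (unit, drug) deviance cells; predictors are one membership
    column per therapeutic class (shared across units, absorbing class-level
    deviance) plus, per unit, a column equal to the drug's brand indicator
    on that unit's rows. With ``grouping='state'`` county deviances are
    first aggregated to states by (optionally weighted) mean.

    Returns a DataFrame (unit, coef, se).
    """
    cat = catalog.set_index("drug_id").loc[list(deviance_matrix.columns)]
    brand = cat["brand_only"].to_numpy(bool)
    if brand.all() or not brand.any():
        raise ValueError("catalog must contain both brand-only and generic drugs")
    if grouping == "state":
        if state_of is None:
            raise ValueError("state grouping requires a county -> state map")
        w = unit_weights.reindex(deviance_matrix.index).fillna(0.0) if unit_weights is not None else None
        groups = state_of.loc[deviance_matrix.index]
        if w is None:
            M = deviance_matrix.groupby(groups).mean()
        else:
            M = deviance_matrix.mul(w, axis=0).groupby(groups).sum().div(
                w.groupby(groups).sum(), axis=0
            )
    elif grouping == "county":
        M = deviance_matrix
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    class_map = catalog_class_map(catalog)
    classes = sorted({c for d in M.columns for c in class_map[d]})
    D, C, U = len(M.columns), len(classes), len(M.index)
    member = np.zeros((D, C))
    for j, d in enumerate(M.columns):
        for c in class_map[d]:
            member[j, classes.index(c)] = 1.0

    # long design: U*D rows, C class columns + U unit-brand columns
    Y = M.to_numpy(float).reshape(-1)          # unit-major
    Xc = np.tile(member, (U, 1))
    Xb = np.kron(np.eye(U), brand.astype(float)[:, None])
    X = np.hstack([Xc, Xb])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "brand/class design is rank-deficient (brand indicator lies in the "
            "span of class memberships); unit coefficients are identified only "
            "up to a shared constant"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(len(Y) - rank, 1)
    sigma2 = float(resid @ resid) / dof
    XtX = X.T @ X
    cov = sigma2 * np.linalg.pinv(XtX)
    se = np.sqrt(np.diag(cov))
    return pd.DataFrame(
        {"unit": list(M.index), "coef": beta[C:], "se": se[C:]}
    ).set_index("unit")


def brand_demographic_model(
    preferences: pd.Series, demographics: pd.DataFrame, seed: int = 0
) -> dict:
    """Elastic net of per-county brand preference on standardized county
    demographics; returns ranked coefficients and in-sample R^2."""
    demo = demographics.loc[preferences.index]
    res = elastic_net_predict(preferences, demo, seed=seed)
    res["coef"] = res["coef"].sort_values(key=np.abs, ascending=False)
    return res


def class_price_correlation(
    projections: pd.DataFrame,
    deviance_matrix: pd.DataFrame,
    catalog: pd.DataFrame,
    component: str = "PC1",
    price_based: bool = False,
) -> dict:
    """Correlate each drug's component association with its brand status.

    Per drug: Spearman correlation of its deviance column with the county
    projection on ``component`` (the drug's component association). Per
    class with >= 3 drugs: Spearman of component association vs brand
    status (or price rank if ``price_based``). Pooled: the same over all
    drugs, with the t-transform p-value.

    Brand status is the continuous ``brand_fraction`` column when the
    catalog supplies one, else the binary ``brand_only`` flag (whose heavy
    ties cap the attainable Spearman correlation well below 1).
    """
    if component not in projections.columns:
        raise KeyError(f"component {component!r} not in projections")
    proj = projections[component].loc[deviance_matrix.index].to_numpy(float)
    cat = catalog.set_index("drug_id").loc[list(deviance_matrix.columns)]
    assoc = np.array(
        [
            spearman_test(deviance_matrix[d].to_numpy(float), proj)[0]
            for d in deviance_matrix.columns
        ]
    )
    assoc = pd.Series(assoc, index=deviance_matrix.columns, name="component_association")
    if price_based:
        feature = cat["price"]
    elif "brand_fraction" in cat.columns:
        feature = cat["brand_fraction"].astype(float)
    else:
        feature = cat["brand_only"].astype(float)

    per_class = []
    class_map = catalog_class_map(catalog)
    classes = sorted({c for d in deviance_matrix.columns for c in class_map[d]})
    for cls in classes:
        drugs = [d for d in deviance_matrix.columns if cls in class_map[d]]
        if len(drugs) < 3:
            per_class.append({"class": cls, "n_drugs": len(drugs), "rho": np.nan,
                              "skipped": True, "reason": "fewer than 3 drugs"})
            continue
        f = feature.loc[drugs]
        if f.nunique() < 2 or assoc.loc[drugs].nunique() < 2:
            per_class.append({"class": cls, "n_drugs": len(drugs), "rho": np.nan,
                              "skipped": True, "reason": "constant feature"})
            continue
        rho, _ = spearman_test(assoc.loc[drugs], f)
        per_class.append({"class": cls, "n_drugs": len(drugs), "rho": rho,
                          "skipped": False, "reason": ""})
    pooled_rho, pooled_p = spearman_test(assoc, feature)
    return {
        "component_association": assoc,
        "per_class": pd.DataFrame(per_class),
        "pooled_rho": pooled_rho,
        "pooled_p": pooled_p,
    }
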