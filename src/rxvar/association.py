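"""Validation statistics linking the deviance matrix to county structure.

Pairwise county distances (deviance / demographic / geographic), Spearman
correlation with its t-transform p-value, the border same-state regression,
therapeutic-class recovery via an adapted Adjusted Rand procedure,
state-group rank-sum tests, elastic-net cross-prediction with drug-set
coefficient tests, and regression imputation of county demographics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.linear_model import ElasticNetCV, MultiTaskElasticNetCV
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "pairwise_distances",
    "build_pair_table",
    "spearman_test",
    "border_samestate_regression",
    "collapse_classes",
    "class_recovery_rand",
    "state_group_ranksum",
    "elastic_net_predict",
    "drugset_coefficient_test",
    "impute_demographics",
]


def pairwise_distances(matrix: pd.DataFrame, mode: str) -> pd.DataFrame:
    """All C(n,2) Euclidean county-pair distances in deterministic order.

    Modes: ``deviance`` (columns z-scored first), ``demographic`` (columns
    z-scored), ``geographic`` (raw lat/lon Euclidean — planar, matching the
    convention of the distance statistic, not great-circle).
    """
    if mode in ("deviance", "demographic"):
        M = stats.zscore(matrix.to_numpy(float), ddof=1, axis=0)
    elif mode == "geographic":
        M = matrix[["lat", "lon"]].to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d = pdist(M, metric="euclidean")
    ids = list(matrix.index)
    ia, ib = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "county_a": np.asarray(ids, dtype=object)[ia],
            "county_b": np.asarray(ids, dtype=object)[ib],
            f"dist_{mode}": d,
        }
    )


def build_pair_table(
    deviance_matrix: pd.DataFrame,
    counties: pd.DataFrame,
    adjacency: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per unordered county pair with all three distances plus
    same-state and border flags (border requires an adjacency table)."""
    cty = counties.set_index("county_id").loc[deviance_matrix.index]
    demo_cols = [c for c in cty.columns if c.startswith("demo_")]
    out = pairwise_distances(deviance_matrix, "deviance")
    out = out.merge(pairwise_distances(cty[demo_cols], "demographic"),
                    on=["county_a", "county_b"])
    out = out.merge(pairwise_distances(cty[["lat", "lon"]], "geographic"),
                    on=["county_a", "county_b"])
    state = cty["state_id"]
    out["same_state"] = (
        state.loc[out["county_a"]].to_numpy() == state.loc[out["county_b"]].to_numpy()
    )
    if adjacency is not None:
        border = {
            frozenset((a, b))
            for a, b in zip(adjacency["county_a"], adjacency["county_b"])
        }
        out["is_border"] = [
            frozenset((a, b)) in border
            for a, b in zip(out["county_a"], out["county_b"])
        ]
    return out


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho with the two-sided p from the t-transform
    t = rho*sqrt((n-2)/(1-rho^2)); ties get midranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def border_samestate_regression(pairs: pd.DataFrame) -> dict:
    """OLS of bordering-pair deviance distance on demographic distance and a
    same-state indicator.

    Pairs are restricted to bordering pairs where at least one county sits
    on a state border (has a cross-state neighbor). Returns coefficients,
    standard errors and p-values; the same-state p is the single-coefficient
    F-test (identical to the two-sided t-test).
    """
    if "is_border" not in pairs.columns:
        raise ValueError("pair table lacks border flags; supply adjacency")
    bp = pairs[pairs["is_border"]].copy()
    cross = bp[~bp["same_state"]]
    border_counties = set(cross["county_a"]) | set(cross["county_b"])
    if not border_counties:
        raise ValueError("no cross-state border pairs; design is degenerate")
    bp = bp[
        bp["county_a"].isin(border_counties) | bp["county_b"].isin(border_counties)
    ]
    X = bp[["dist_demographic", "same_state"]].astype(float)
    dropped = []
    if X["dist_demographic"].nunique() <= 1:
        dropped.append("dist_demographic")
        X = X.drop(columns=["dist_demographic"])
    if X["same_state"].nunique() <= 1:
        raise ValueError("same-state indicator is constant among border pairs")
    if len(bp) < X.shape[1] + 3:
        raise ValueError(f"only {len(bp)} border pairs; design is degenerate")
    fit = sm.OLS(bp["dist_deviance"].to_numpy(float), sm.add_constant(X)).fit()
    ftest = fit.f_test("same_state = 0")
    return {
        "coef": fit.params.to_dict(),
        "se": fit.bse.to_dict(),
        "p": fit.pvalues.to_dict(),
        "same_state_F_p": float(np.squeeze(ftest.pvalue)),
        "n_pairs": int(len(bp)),
        "dropped": dropped,
    }


def collapse_classes(class_map: dict[str, list[str]], target: int) -> dict[str, list[str]]:
    """Greedily merge the class pair with highest Jaccard overlap until at
    most ``target`` classes remain; returns a new drug -> classes map with
    merged labels joined by '+'."""
    members: dict[str, set[str]] = {}
    for d, cls in class_map.items():
        for c in cls:
            members.setdefault(c, set()).add(d)
    while len(members) > target:
        names = sorted(members)
        best, best_j = None, -1.0
        for i in range(len(names)):
            si = members[names[i]]
            for j in range(i + 1, len(names)):
                sj = members[names[j]]
                inter = len(si & sj)
                jac = inter / len(si | sj) if (si or sj) else 0.0
                if jac > best_j:
                    best_j, best = jac, (names[i], names[j])
        a, b = best
        members[f"{a}+{b}"] = members.pop(a) | members.pop(b)
    out: dict[str, list[str]] = {d: [] for d in class_map}
    for c, drugs in sorted(members.items()):
        for d in drugs:
            out[d].append(c)
    return out


def class_recovery_rand(
    deviance_matrix: pd.DataFrame,
    class_map: dict[str, list[str]],
    n_classes_target: int,
    n_assign: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
    linkage_method: str = "average",
) -> dict:
    """Do drugs of a therapeutic class cluster together by county profile?

    Overlapping classes are first greedily collapsed to ``n_classes_target``;
    drugs' county-deviance vectors are hierarchically clustered (average
    linkage, Euclidean) and the tree cut to the collapsed class count. For
    each of ``n_assign`` randomized single-class assignments (each
    multi-class drug assigned to one of its classes at random) the Adjusted
    Rand index against the clustering is computed; the null repeats this
    with permuted class labels ``n_perm`` times. The separation statistic is
    a one-sided rank-sum p of observed ARIs above the permutation null.
    """
    drugs = list(deviance_matrix.columns)
    if len(drugs) < 3:
        raise ValueError("need at least 3 drugs to cluster")
    if n_assign < 1 or n_perm < 1:
        raise ValueError("n_assign and n_perm must be >= 1")
    collapsed = collapse_classes({d: class_map[d] for d in drugs}, n_classes_target)
    n_cls = len({c for cls in collapsed.values() for c in cls})

    X = stats.zscore(deviance_matrix.to_numpy(float), ddof=1, axis=0).T  # drugs x counties
    Z = linkage(X, method=linkage_method, metric="euclidean")
    clusters = fcluster(Z, t=n_cls, criterion="maxclust")

    rng = np.random.default_rng(seed)
    choices = [collapsed[d] for d in drugs]
    observed = np.empty(n_assign)
    for i in range(n_assign):
        labels = [c[rng.integers(len(c))] for c in choices]
        observed[i] = adjusted_rand_score(labels, clusters)
    null = np.empty(n_perm)
    base_labels = np.array([c[rng.integers(len(c))] for c in choices], dtype=object)
    for i in range(n_perm):
        null[i] = adjusted_rand_score(base_labels[rng.permutation(len(drugs))], clusters)
    sep = stats.mannwhitneyu(observed, null, alternative="greater")
    return {
        "observed_ari": observed,
        "null_ari": null,
        "separation_p": float(sep.pvalue),
        "n_collapsed_classes": n_cls,
        "clusters": pd.Series(clusters, index=drugs, name="cluster"),
    }


def state_group_ranksum(
    state_values: pd.Series, state_subset: list[str], alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum of a state subset's deviance values against the
    complement (midranks; exact for small untied samples, normal
    approximation with continuity correction otherwise)."""
    subset = [s for s in state_subset if s in state_values.index]
    if not subset:
        raise ValueError("state subset is empty or disjoint from the data")
    if len(subset) >= len(state_values):
        raise ValueError("state subset must be a proper subset")
    a = state_values.loc[subset].to_numpy(float)
    b = state_values.drop(index=subset).to_numpy(float)
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method="auto").pvalue)


def elastic_net_predict(
    target: pd.Series | pd.DataFrame,
    predictors: pd.DataFrame,
    l1_ratio: float = 0.5,
    cv: int = 5,
    seed: int = 0,
) -> dict:
    """Elastic net of a county-level target on z-scored predictors.

    Predictors are standardized internally so coefficients are directly
    comparable across predictors. A DataFrame target uses the multi-task
    variant (shared sparsity across targets). Returns standardized
    coefficients and in-sample R^2.
    """
    if len(predictors) < 10:
        raise ValueError("fewer than 10 counties; elastic-net CV is unstable")
    X = stats.zscore(predictors.to_numpy(float), ddof=1, axis=0)
    multi = isinstance(target, pd.DataFrame)
    yv = target.to_numpy(float)
    if multi:
        model = MultiTaskElasticNetCV(l1_ratio=l1_ratio, cv=cv, random_state=seed,
                                      max_iter=5000)
    else:
        model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, random_state=seed,
                             max_iter=5000)
    model.fit(X, yv)
    r2 = float(model.score(X, yv))
    coef = model.coef_.T if multi else model.coef_
    if multi:
        coefs = pd.DataFrame(coef, index=predictors.columns, columns=target.columns)
    else:
        coefs = pd.Series(coef, index=predictors.columns, name="coef")
    return {"coef": coefs, "r2": r2, "alpha": float(model.alpha_)}


def drugset_coefficient_test(coefficients: pd.Series, drug_set: list[str]) -> float:
    """Two-tailed rank-sum: are the coefficients of a drug set collectively
    high or low relative to all other drugs' coefficients?"""
    inset = [d for d in drug_set if d in coefficients.index]
    if not inset:
        raise ValueError("drug set is empty or disjoint from the coefficients")
    if len(inset) >= len(coefficients):
        raise ValueError("drug set must be a proper subset")
    a = coefficients.loc[inset].to_numpy(float)
    b = coefficients.drop(index=inset).to_numpy(float)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def impute_demographics(
    county_table: pd.DataFrame, max_missing: int = 10
) -> pd.DataFrame:
    """Regression imputation of county demographics.

    Variables with more than ``max_missing`` missing counties are dropped;
    each remaining missing cell is filled from an OLS regression on the
    fully observed variables, fit over counties observed on the target
    variable. Deterministic.
    """
    demo_cols = [c for c in county_table.columns if c.startswith("demo_")]
    tab = county_table.copy()
    miss = tab[demo_cols].isna().sum()
    keep = [c for c in demo_cols if miss[c] <= max_missing]
    tab = tab.drop(columns=[c for c in demo_cols if c not in keep])
    all_missing = tab[keep].isna().all(axis=1)
    if all_missing.any():
        bad = tab.loc[all_missing, "county_id"].tolist() if "county_id" in tab else list(tab.index[all_missing])
        raise ValueError(f"counties missing all demographics: {bad[:5]}")
    complete = [c for c in keep if tab[c].notna().all()]
    for c in keep:
        if c in complete:
            continue
        obs = tab[c].notna()
        X = sm.add_constant(tab.loc[obs, complete].to_numpy(float))
        beta, *_ = np.linalg.lstsq(X, tab.loc[obs, c].to_numpy(float), rcond=None)
        Xm = sm.add_constant(tab.loc[~obs, complete].to_numpy(float), has_constant="add")
        tab.loc[~obs, c] = Xm @ beta
    return tab
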