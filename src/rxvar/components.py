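"""Latent axes of regional prescribing from the deviance matrix.

PCA via SVD of the column-standardized counties x drugs deviance matrix
(drugs centered and scaled to unit variance), leave-class-out stability of
the drug loadings, and canonical correlation between the deviance block and
the county demographics block with Wilks'-lambda / Rao-F significance and an
optional permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComponentBasis",
    "CCAFilter",
    "CCAResult",
    "fit_components",
    "stability_leave_class_out",
    "canonical_correlation",
]


@dataclass
class ComponentBasis:
    loadings: pd.DataFrame          # drugs x k, orthonormal columns
    variance_fraction: np.ndarray   # all components (sums to 1)
    means: pd.Series
    sds: pd.Series

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def _standardize_columns(M: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    zero = sds[sds == 0].index
    if len(zero):
        warnings.warn(f"dropping {len(zero)} zero-variance columns: {list(zero[:5])}")
        M = M.drop(columns=zero)
        means = means.drop(zero)
        sds = sds.drop(zero)
    return (M - means) / sds, means, sds


def fit_components(deviance_matrix: pd.DataFrame, k: int):
    """PCA of the deviance matrix; returns (basis, county projections).

    Columns (drugs) are centered and variance-standardized, then the
    economy SVD supplies orthonormal drug loadings and county projections.
    Each component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    if k > min(deviance_matrix.shape):
        raise ValueError(f"k = {k} exceeds matrix rank bound {min(deviance_matrix.shape)}")
    Z, means, sds = _standardize_columns(deviance_matrix)
    X = Z.to_numpy(float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    V = Vt[:k].T  # drugs x k
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip
    loadings = pd.DataFrame(V, index=Z.columns, columns=[f"PC{i+1}" for i in range(k)])
    proj = pd.DataFrame(X @ V, index=Z.index, columns=loadings.columns)
    basis = ComponentBasis(loadings, var_frac, means, sds)
    return basis, proj


def stability_leave_class_out(
    deviance_matrix: pd.DataFrame,
    class_map: dict[str, list[str]],
    k: int,
    dot_threshold: float = 0.95,
) -> pd.DataFrame:
    """Loading stability under removal of one therapeutic class at a time.

    For each class, PCA is refit on the submatrix without that class's
    drugs; per component we report |dot| between the full-model loading
    restricted to the shared drugs (renormalized) and the reduced-model
    loading. Classes leaving fewer than k+1 drugs, or covering all drugs,
    are skipped with a warning.
    """
    full_basis, _ = fit_components(deviance_matrix, k)
    drugs = list(full_basis.loadings.index)
    classes = sorted({c for cls in class_map.values() for c in cls})
    rows = []
    for cls in classes:
        keep = [d for d in drugs if cls not in class_map.get(d, [])]
        if len(keep) == len(drugs):
            # empty class: reduced model is the full model
            for i in range(k):
                rows.append({"class": cls, "component": i + 1, "abs_dot": 1.0,
                             "n_removed": 0})
            continue
        if len(keep) == 0:
            warnings.warn(f"class {cls} covers all drugs; skipped")
            continue
        if len(keep) < k + 1:
            warnings.warn(f"class {cls} leaves {len(keep)} drugs (< k+1); skipped")
            continue
        red_basis, _ = fit_components(deviance_matrix[keep], k)
        for i in range(k):
            v_full = full_basis.loadings.loc[keep].iloc[:, i].to_numpy()
            nrm = np.linalg.norm(v_full)
            v_full = v_full / nrm if nrm > 0 else v_full
            v_red = red_basis.loadings.iloc[:, i].to_numpy()
            rows.append(
                {
                    "class": cls,
                    "component": i + 1,
                    "abs_dot": float(abs(v_full @ v_red)),
                    "n_removed": len(drugs) - len(keep),
                }
            )
    report = pd.DataFrame(rows)
    if len(report):
        report.attrs["fraction_stable"] = float(
            (report["abs_dot"] > dot_threshold).mean()
        )
    return report


@dataclass
class CCAFilter:
    """Row/column filtering ahead of CCA.

    ``usage_quantile`` keeps drugs above that quantile of ``user_counts``
    (mirroring a most-used-drugs restriction); ``collinearity_r`` drops one
    of any demographic pair correlated above the threshold;
    ``min_row_ratio`` requires rows >= ratio * columns in each block.
    """

    user_counts: pd.Series | None = None
    usage_quantile: float = 0.0
    collinearity_r: float = 0.95
    min_row_ratio: float = 2.0


@dataclass
class CCAResult:
    correlations: np.ndarray
    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    significance: pd.DataFrame     # per dimension: wilks, F, df1, df2, p
    permutation_p: np.ndarray | None = None
    kept_x: list[str] = field(default_factory=list)
    kept_y: list[str] = field(default_factory=list)


def _drop_collinear(M: pd.DataFrame, r_max: float) -> pd.DataFrame:
    corr = M.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    cols = list(M.columns)
    drop: set[str] = set()
    for i in range(len(cols)):
        if cols[i] in drop:
            continue
        for j in range(i + 1, len(cols)):
            if cols[j] in drop:
                continue
            if corr[i, j] > r_max:
                drop.add(cols[j])
    return M.drop(columns=list(drop))


def _canonical_correlations(X: np.ndarray, Y: np.ndarray):
    n = X.shape[0]
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    try:
        Lx = np.linalg.cholesky(Sxx)
        Ly = np.linalg.cholesky(Syy)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular within-block covariance; apply stronger collinearity/usage filtering"
        ) from e
    M = np.linalg.solve(Lx, Sxy) @ np.linalg.inv(Ly).T
    U, s, Vt = np.linalg.svd(M)
    r = np.clip(s, 0.0, 1.0)
    A = np.linalg.solve(Lx.T, U)       # x canonical weights
    B = np.linalg.solve(Ly.T, Vt.T)    # y canonical weights
    return r, A, B


def _wilks_table(r: np.ndarray, n: int, p: int, q: int) -> pd.DataFrame:
    """Rao's F approximation to Wilks' lambda, testing dimensions k..min(p,q)."""
    m = len(r)
    rows = []
    lam_tail = np.cumprod((1.0 - r**2)[::-1])[::-1]  # lam_tail[k] = prod_{i>=k}(1-r_i^2)
    for k in range(m):
        p1, q1 = p - k, q - k
        L = float(lam_tail[k])
        de = p1 * q1
        denom = p1**2 + q1**2 - 5
        t = np.sqrt((p1**2 * q1**2 - 4) / denom) if denom > 0 else 1.0
        w = n - 1.5 - (p1 + q1) / 2.0
        df1 = de
        df2 = w * t - de / 2.0 + 1.0
        if df2 <= 0 or L <= 0:
            F, pval = np.nan, np.nan
        else:
            Lt = L ** (1.0 / t)
            F = (1.0 - Lt) / Lt * df2 / df1
            pval = float(stats.f.sf(F, df1, df2))
        rows.append({"dimension": k + 1, "wilks": L, "F": F, "df1": df1,
                     "df2": df2, "p": pval})
    return pd.DataFrame(rows)


def canonical_correlation(
    deviance_sub: pd.DataFrame,
    demographics: pd.DataFrame,
    filter_spec: CCAFilter | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> CCAResult:
    """CCA between county deviance and demographic blocks.

    Both blocks are filtered (usage quantile on drugs, collinearity on
    demographics), z-scored, and whitened; canonical correlations come from
    the SVD of the whitened cross-covariance. Per-dimension significance
    uses Wilks' lambda with Rao's F approximation; with ``n_perm`` > 0 a
    permutation test (county rows of the demographic block permuted) is
    added, which is preferable at small n.
    """
    fs = filter_spec or CCAFilter()
    if not deviance_sub.index.equals(demographics.index):
        raise ValueError("county rows of the two blocks must be aligned")
    Xdf = deviance_sub
    if fs.user_counts is not None and fs.usage_quantile > 0:
        thr = fs.user_counts.quantile(fs.usage_quantile)
        keep = fs.user_counts[fs.user_counts >= thr].index
        Xdf = Xdf[[c for c in Xdf.columns if c in set(keep)]]
    Ydf = _drop_collinear(demographics, fs.collinearity_r)
    n = len(Xdf)
    for name, block in (("deviance", Xdf), ("demographics", Ydf)):
        if n < fs.min_row_ratio * block.shape[1]:
            raise ValueError(
                f"{name} block has {block.shape[1]} columns for {n} counties; "
                f"need rows >= {fs.min_row_ratio} x columns — filter harder"
            )
    X = stats.zscore(Xdf.to_numpy(float), ddof=1)
    Y = stats.zscore(Ydf.to_numpy(float), ddof=1)
    r, A, B = _canonical_correlations(X, Y)
    sig = _wilks_table(r, n, X.shape[1], Y.shape[1])

    perm_p = None
    if n_perm > 0:
        # per-dimension largest-root statistic: permuted r_k vs observed r_k
        rng = np.random.default_rng(seed)
        count = np.zeros(len(r))
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            rp, _, _ = _canonical_correlations(X, Yp)
            count += rp >= r
        perm_p = (1.0 + count) / (n_perm + 1.0)

    return CCAResult(
        correlations=r,
        x_weights=pd.DataFrame(A, index=Xdf.columns,
                               columns=[f"cc{i+1}" for i in range(A.shape[1])]),
        y_weights=pd.DataFrame(B, index=Ydf.columns,
                               columns=[f"cc{i+1}" for i in range(B.shape[1])]),
        significance=sig,
        permutation_p=perm_p,
        kept_x=list(Xdf.columns),
        kept_y=list(Ydf.columns),
    )
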