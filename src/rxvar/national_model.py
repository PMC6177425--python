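"""Per-drug national incidence model ("USA model").

Each drug's probability of first use per person-year is modelled as a
logistic regression on the four bin variables (age band, calendar year,
incident-prescription count r, incident-year count m) coded as categorical
dummies with all six pairwise interactions — the discrete-time survival
formulation of first-use incidence. The fit is ridge-penalized with the
penalty chosen by seeded cross-validation on held-out binomial deviance,
and the penalty is scaled per observation so that fitting grouped (n, y)
bin counts equals fitting exploded Bernoulli rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FitHyper",
    "DrugModel",
    "DegenerateFitError",
    "fit_drug_model",
    "predict_bin_probability",
    "holdout_bias_check",
]

FACTORS = ["age_band", "year", "r_level", "m_level"]
_LINPRED_CLIP = 30.0


class DegenerateFitError(ValueError):
    """Raised when a drug has no events nationally; exclude the drug."""


@dataclass
class FitHyper:
    """Hyperparameters of the per-drug ridge logistic fit.

    ``lambdas`` are per-observation L2 penalties (the sklearn ``C`` is
    derived as 1 / (lambda * total person-years)).
    """

    lambdas: tuple[float, ...] = (1e-6, 1e-4, 1e-2)
    n_folds: int = 3
    seed: int = 0
    max_iter: int = 2000


@dataclass
class DrugModel:
    drug_id: str
    levels: dict[str, np.ndarray]        # factor -> sorted observed levels
    coef: np.ndarray
    intercept: float
    column_names: list[str]
    lambda_: float
    cv_deviance: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "levels": {k: v.tolist() for k, v in self.levels.items()},
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "column_names": self.column_names,
            "lambda": self.lambda_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugModel":
        return cls(
            drug_id=d["drug_id"],
            levels={k: np.asarray(v) for k, v in d["levels"].items()},
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            column_names=list(d["column_names"]),
            lambda_=float(d["lambda"]),
        )


def _snap_levels(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Map values to the nearest observed level (factors are ordinal)."""
    idx = np.searchsorted(levels, values)
    idx = np.clip(idx, 0, len(levels) - 1)
    lo = np.clip(idx - 1, 0, len(levels) - 1)
    pick_lo = np.abs(values - levels[lo]) <= np.abs(levels[idx] - values)
    return np.where(pick_lo, levels[lo], levels[idx])


def _design(bins: pd.DataFrame, levels: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Dummy design with first-level reference and all pairwise interactions."""
    blocks: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for f in FACTORS:
        lev = levels[f]
        vals = _snap_levels(bins[f].to_numpy(float), lev.astype(float))
        dummies = (vals[:, None] == lev.astype(float)[None, 1:]).astype(float)
        blocks[f] = dummies
        names[f] = [f"{f}={int(v)}" for v in lev[1:]]
    cols = [blocks[f] for f in FACTORS]
    colnames = [n for f in FACTORS for n in names[f]]
    for i in range(len(FACTORS)):
        for j in range(i + 1, len(FACTORS)):
            a, b = blocks[FACTORS[i]], blocks[FACTORS[j]]
            if a.shape[1] == 0 or b.shape[1] == 0:
                continue
            inter = a[:, :, None] * b[:, None, :]
            cols.append(inter.reshape(len(bins), -1))
            colnames += [
                f"{na}:{nb}" for na in names[FACTORS[i]] for nb in names[FACTORS[j]]
            ]
    X = np.hstack(cols) if cols else np.zeros((len(bins), 0))
    if X.shape[1] == 0:
        # saturated single-bin case: all-zero column leaves intercept-only fit
        X = np.zeros((len(bins), 1))
        colnames = ["_null"]
    return X, colnames


def _explode(X: np.ndarray, n: np.ndarray, y: np.ndarray):
    """Two weighted rows (event / non-event) per bin; zero weights dropped."""
    Xr = np.vstack([X, X])
    out = np.concatenate([np.ones(len(X)), np.zeros(len(X))])
    w = np.concatenate([y.astype(float), (n - y).astype(float)])
    keep = w > 0
    return Xr[keep], out[keep], w[keep]


def _binomial_deviance(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def _fit_weighted(X, out, w, C, max_iter):
    clf = LogisticRegression(
        penalty="l2", C=C, solver="lbfgs", max_iter=max_iter, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, out, sample_weight=w)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def fit_drug_model(
    national_counts: pd.DataFrame,
    drug_id: str,
    bin_lookup: pd.DataFrame,
    hyper: FitHyper | None = None,
) -> DrugModel:
    """Fit one drug's penalized binomial model on grouped bin counts.

    Parameters
    ----------
    national_counts
        Long frame (drug_id, bin_id, n, y) of national risk-set counts.
    bin_lookup
        bin_id -> factor levels (age_band, year, r_level, m_level).
    """
    hyper = hyper or FitHyper()
    sub = national_counts[national_counts["drug_id"] == drug_id]
    if len(sub) == 0:
        raise KeyError(f"no risk-set rows for drug {drug_id}")
    sub = sub.merge(bin_lookup, on="bin_id", how="left", validate="many_to_one")
    if sub[FACTORS].isna().any().any():
        raise KeyError(f"bins missing from lookup for drug {drug_id}")
    n = sub["n"].to_numpy(float)
    y = sub["y"].to_numpy(float)
    if y.sum() == 0:
        raise DegenerateFitError(
            f"drug {drug_id} has zero events nationally; exclude it from modelling"
        )
    levels = {f: np.sort(sub[f].unique()) for f in FACTORS}
    X, colnames = _design(sub, levels)
    N = n.sum()

    rng = np.random.default_rng(hyper.seed)
    cv_dev: dict[float, float] = {}
    if len(hyper.lambdas) > 1:
        # split each bin's trials (and its events hypergeometrically) into folds
        K = hyper.n_folds
        fold_n = np.vstack([rng.multinomial(int(ni), np.full(K, 1.0 / K)) for ni in n])
        fold_y = np.vstack(
            [rng.multivariate_hypergeometric(fn, int(yi)) for fn, yi in zip(fold_n, y)]
        )
        for lam in hyper.lambdas:
            dev = 0.0
            ok = True
            for k in range(K):
                ntr = n - fold_n[:, k]
                ytr = y - fold_y[:, k]
                if ytr.sum() == 0 or fold_n[:, k].sum() == 0:
                    ok = False
                    break
                Xe, oe, we = _explode(X, ntr, ytr)
                C = 1.0 / (max(lam, 1e-300) * we.sum())
                coef, icpt = _fit_weighted(Xe, oe, we, C, hyper.max_iter)
                eta = np.clip(X @ coef + icpt, -_LINPRED_CLIP, _LINPRED_CLIP)
                p = 1.0 / (1.0 + np.exp(-eta))
                dev += _binomial_deviance(fold_y[:, k], fold_n[:, k], p)
            cv_dev[lam] = dev if ok else np.inf
        best = min(cv_dev, key=lambda l: cv_dev[l])
    else:
        best = hyper.lambdas[0]

    Xe, oe, we = _explode(X, n, y)
    C = 1.0 / (max(best, 1e-300) * we.sum())
    coef, icpt = _fit_weighted(Xe, oe, we, C, hyper.max_iter)
    return DrugModel(
        drug_id=drug_id,
        levels=levels,
        coef=coef,
        intercept=icpt,
        column_names=colnames,
        lambda_=best,
        cv_deviance=cv_dev,
    )


def predict_bin_probability(model: DrugModel, bins: pd.DataFrame) -> np.ndarray:
    """p-hat per bin row; unseen factor levels snap to the nearest observed
    level, and the linear predictor is clipped so probabilities stay inside
    (0, 1)."""
    X, _ = _design(bins, model.levels)
    eta = X @ model.coef + model.intercept
    eta = np.clip(eta, -_LINPRED_CLIP, _LINPRED_CLIP)
    return 1.0 / (1.0 + np.exp(-eta))


def holdout_bias_check(
    models: dict[str, DrugModel],
    holdout_counts: pd.DataFrame,
    bin_lookup: pd.DataFrame,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Predicted vs observed holdout event totals per drug, with binomial z.

    ``holdout_counts`` must come from persons disjoint from the training
    cohort. Drugs with near-zero predicted totals get ratio NaN but keep
    their counts.
    """
    if len(holdout_counts) == 0:
        raise ValueError("empty holdout risk sets")
    rows = []
    for drug_id, model in models.items():
        sub = holdout_counts[holdout_counts["drug_id"] == drug_id]
        if len(sub) == 0:
            continue
        sub = sub.merge(bin_lookup, on="bin_id", how="left", validate="many_to_one")
        p = predict_bin_probability(model, sub)
        n = sub["n"].to_numpy(float)
        y_obs = float(sub["y"].sum())
        y_pred = float(np.sum(n * p))
        var = float(np.sum(n * p * (1 - p)))
        z = (y_obs - y_pred) / np.sqrt(var) if var > 0 else np.nan
        ratio = y_obs / y_pred if y_pred > 1e-9 else np.nan
        rows.append(
            {
                "drug_id": drug_id,
                "observed": y_obs,
                "predicted": y_pred,
                "ratio": ratio,
                "z": z,
                "flagged": bool(np.isfinite(z) and abs(z) > z_threshold),
            }
        )
    return pd.DataFrame(rows)
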