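"""Microbe-metabolite association screening.

Covariate-adjusted fixed-effect linear models between log10 OTU
proportions and serum metabolites: per pair, metabolite ~ log10(feature)
+ age + body_weight + stage, with BH control across all (feature,
metabolite) pairs and a joint significance rule q <= 0.05 and |r| >= 0.2,
where r is the signed partial correlation of the feature term.  Zeros
are replaced per feature by half its smallest non-zero proportion before
the log.  A Spearman screen covers monotone associations against any
numeric table (alpha diversity, echo variables).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .taxa import bh_adjust

MIN_RELATIVE_ABUNDANCE = 1e-4   # 0.01 %
MIN_PREVALENCE = 0.10

Q_THRESHOLD = 0.05
R_THRESHOLD = 0.2


class AbundanceFilter(BaseEstimator, TransformerMixin):
    """Keep features whose relative abundance reaches 0.01% in at least
    10% of samples (both boundaries inclusive)."""

    def __init__(self, min_abundance: float = MIN_RELATIVE_ABUNDANCE,
                 min_prevalence: float = MIN_PREVALENCE):
        self.min_abundance = min_abundance
        self.min_prevalence = min_prevalence

    def fit(self, X: pd.DataFrame, y=None):
        arr = X.to_numpy(dtype=float)
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("expected relative abundances in [0, 1]")
        frac = (arr >= self.min_abundance).mean(axis=0)
        keep = frac >= self.min_prevalence
        self.kept_features_ = list(X.columns[keep])
        self.dropped_features_ = list(X.columns[~keep])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_features_]


def abundance_filter(rel_abund: pd.DataFrame) -> pd.DataFrame:
    return AbundanceFilter().fit_transform(rel_abund)


def log10_with_pseudocount(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """log10 proportions; zeros replaced per feature by half the smallest
    non-zero proportion of that feature.  All-zero features are dropped
    with a warning."""
    out = {}
    for col in rel_abund.columns:
        x = rel_abund[col].to_numpy(dtype=float).copy()
        nz = x[x > 0]
        if len(nz) == 0:
            warnings.warn(f"feature {col!r} is all-zero; dropped")
            continue
        x[x == 0] = nz.min() / 2.0
        out[col] = np.log10(x)
    return pd.DataFrame(out, index=rel_abund.index)


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    # constant covariates are absorbed by the intercept, not an error
    cols = [np.ones(len(covariates))]
    for name in ("age", "body_weight"):
        x = covariates[name].to_numpy(dtype=float)
        if np.ptp(x) > 0:
            cols.append(x)
    codes, uniques = pd.factorize(covariates["stage"], sort=True)
    for kk in range(1, len(uniques)):
        cols.append((codes == kk).astype(float))
    return np.column_stack(cols)


def associate(features: pd.DataFrame, metabolites: pd.DataFrame,
              covariates: pd.DataFrame) -> pd.DataFrame:
    """Fit every (feature, metabolite) linear model and apply the joint rule.

    ``features`` are relative abundances (already abundance-filtered);
    ``covariates`` must provide age, body_weight and stage.  Returns a
    long table (feature, metabolite, coefficient, r, p, q, significant).
    Rank-deficient designs are skipped with a warning.
    """
    ids = features.index.intersection(metabolites.index).intersection(covariates.index)
    if len(ids) < 10:
        raise ValueError("need at least 10 complete samples")
    feats = log10_with_pseudocount(features.loc[ids])
    y_mat = metabolites.loc[ids].to_numpy(dtype=float)
    z = _covariate_design(covariates.loc[ids])
    n = len(ids)
    rows = []
    for feat in feats.columns:
        x = np.column_stack([feats[feat].to_numpy(), z])  # feature first
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            warnings.warn(f"rank-deficient design for feature {feat!r}; skipped")
            continue
        df_resid = n - x.shape[1]
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ y_mat)           # p x m, all metabolites at once
        resid = y_mat - x @ beta
        sigma2 = (resid ** 2).sum(axis=0) / df_resid
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[0] / se, np.inf * np.sign(beta[0]))
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        with np.errstate(invalid="ignore"):
            r = np.sign(beta[0]) * np.sqrt(t ** 2 / (t ** 2 + df_resid))
        r = np.where(np.isfinite(t), r, np.sign(beta[0]))
        for m, met in enumerate(metabolites.columns):
            rows.append({"feature": feat, "metabolite": met,
                         "coefficient": float(beta[0, m]), "r": float(r[m]),
                         "p": float(min(p[m], 1.0))})
    out = pd.DataFrame(rows, columns=["feature", "metabolite", "coefficient", "r", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"])
        out["significant"] = (out["q"] <= Q_THRESHOLD) & (out["r"].abs() >= R_THRESHOLD)
    else:
        out["q"] = []
        out["significant"] = []
    return out


def spearman_screen(x: pd.DataFrame, y: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho (Pearson on mid-ranks) for every (x, y) column pair,
    p via the t transform, BH across pairs; constant columns skipped."""
    ids = x.index.intersection(y.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 shared samples")
    xs, ys = x.loc[ids], y.loc[ids]
    rows = []
    for cx in xs.columns:
        if xs[cx].std(ddof=0) == 0:
            warnings.warn(f"constant column {cx!r}; skipped")
            continue
        for cy in ys.columns:
            if ys[cy].std(ddof=0) == 0:
                warnings.warn(f"constant column {cy!r}; skipped")
                continue
            rho, p = stats.spearmanr(xs[cx], ys[cy])
            rows.append({"x": cx, "y": cy, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows, columns=["x", "y", "rho", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = []
    return out
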