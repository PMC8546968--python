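"""Bile-acid pool arithmetic and converter-threshold estimation.

Percentages are taken on the five unconjugated bile acids (CA, CDCA
primary; DCA, LCA, UDCA secondary); the primary/secondary ratio uses a
floored denominator so a fully unconverted pool yields a large finite
ratio instead of infinity.  ``estimate_conversion_threshold`` formalizes
the visually reported converter cutoff as a least-squares step-function
fit on the converter bacterium's log10 abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .io import BILE_ACIDS, PRIMARY_BAS, SECONDARY_BAS, QPCR_TARGETS
from .dysbiosis import pearson_table

#: relative floor for the ratio denominator, as a fraction of the pool
EPSILON_POOL_FRACTION = 0.001


def ba_summary(profile: pd.DataFrame,
               epsilon_pool_fraction: float = EPSILON_POOL_FRACTION) -> pd.DataFrame:
    """Percentages, primary/secondary sums, and the 1-degree/2-degree ratio.

    A zero total pool marks percentages and ratio as NaN (undefined).
    """
    missing = set(BILE_ACIDS) - set(profile.columns)
    if missing:
        raise ValueError(f"missing bile-acid column(s): {sorted(missing)}")
    conc = profile[list(BILE_ACIDS)].astype(float)
    if (conc.to_numpy() < 0).any():
        raise ValueError("negative bile-acid concentration")
    primary = conc[list(PRIMARY_BAS)].sum(axis=1)
    secondary = conc[list(SECONDARY_BAS)].sum(axis=1)
    total = primary + secondary
    out = pd.DataFrame(index=profile.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        for ba in BILE_ACIDS:
            out[f"pct_{ba}"] = np.where(total > 0, 100.0 * conc[ba] / total, np.nan)
    out["primary_sum"] = primary
    out["secondary_sum"] = secondary
    eps = np.maximum(epsilon_pool_fraction * total, 1e-9)
    out["ratio_1_2"] = np.where(total > 0, primary / np.maximum(secondary, eps), np.nan)
    return out


def ba_correlations(summary: pd.DataFrame, di: pd.DataFrame = None,
                    panel: pd.DataFrame = None) -> pd.DataFrame:
    """Pearson correlations of BA percentages and ratio against DI and
    against each qPCR target's log10 abundance (pairwise-complete)."""
    ba_cols = [c for c in summary.columns if c.startswith("pct_")] + ["ratio_1_2"]
    frames = []
    if di is not None:
        ids = summary.index.intersection(di.index)
        if len(ids) < 3:
            raise ValueError("need at least 3 shared samples with DI")
        frames.append(pearson_table(di.loc[ids, "di"], summary.loc[ids, ba_cols], y_name="di"))
    if panel is not None:
        ids = summary.index.intersection(panel.index)
        if len(ids) < 3:
            raise ValueError("need at least 3 shared samples with the qPCR panel")
        for target in (c for c in QPCR_TARGETS if c in panel.columns):
            frames.append(
                pearson_table(panel.loc[ids, target], summary.loc[ids, ba_cols], y_name=target)
            )
    if not frames:
        raise ValueError("provide di and/or panel")
    return pd.concat(frames, ignore_index=True)


@dataclass
class ThresholdFit:
    tau_hat: float
    mean_low: float
    mean_high: float
    rss: float


class StepThresholdRegressor(BaseEstimator, RegressorMixin):
    """Two-segment step model ``y = mean(y | x < tau), mean(y | x >= tau)``.

    The change point is found by exhaustive search over the midpoints of
    consecutive sorted unique x values, minimizing the residual sum of
    squares; ties break to the smallest candidate.  Fitted attributes:
    ``tau_``, ``mean_low_``, ``mean_high_``, ``rss_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if len(x) < 4:
            raise ValueError("need at least 4 points")
        ux = np.unique(x)
        if len(ux) < 2:
            raise ValueError("x must not be constant")
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # candidate thresholds: midpoints between consecutive distinct x
        candidates = (ux[:-1] + ux[1:]) / 2.0
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys ** 2)
        n = len(ys)
        best = (np.inf, None)
        for tau in candidates:
            k = int(np.searchsorted(xs, tau))  # points with x < tau
            s_lo, s2_lo = csum[k - 1], csum2[k - 1]
            s_hi, s2_hi = csum[-1] - s_lo, csum2[-1] - s2_lo
            rss = (s2_lo - s_lo ** 2 / k) + (s2_hi - s_hi ** 2 / (n - k))
            if rss < best[0] - 1e-12:
                best = (rss, tau, k)
        rss, tau, k = best
        self.tau_ = float(tau)
        self.mean_low_ = float(csum[k - 1] / k)
        self.mean_high_ = float((csum[-1] - csum[k - 1]) / (n - k))
        self.rss_ = float(max(rss, 0.0))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return np.where(x < self.tau_, self.mean_low_, self.mean_high_)


def estimate_conversion_threshold(x, y) -> ThresholdFit:
    """Least-squares step fit of a response against converter abundance.

    Typical use: x = C. hiranonis log10 abundance, y = primary-BA
    percentage of the pool; tau_hat estimates the abundance above which
    conversion to secondary bile acids is essentially complete.
    """
    est = StepThresholdRegressor().fit(x, y)
    return ThresholdFit(est.tau_, est.mean_low_, est.mean_high_, est.rss_)


def conversion_analysis(summary: pd.DataFrame, panel: pd.DataFrame) -> ThresholdFit:
    """Fit the converter threshold on shared samples with a defined pool."""
    ids = summary.index.intersection(panel.index)
    sub = summary.loc[ids]
    ok = sub["pct_ca"].notna()
    if ok.sum() < 4:
        warnings.warn("fewer than 4 samples with a defined bile-acid pool")
    x = panel.loc[ids, "c_hiranonis"][ok]
    y = (sub.loc[ok, "pct_ca"] + sub.loc[ok, "pct_cdca"])
    return estimate_conversion_threshold(x.to_numpy(), y.to_numpy())
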