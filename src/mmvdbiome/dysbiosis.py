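"""qPCR-panel dysbiosis index (DI).

The published DI formula for this panel is proprietary to its reference
laboratory, so the index here is a documented surrogate with the same
sign convention (negative = normal profile) and the same category
cut-points: each of the 8 targets is scaled by a reference standard
deviation, and DI = ln(d_N / d_D), the log ratio of Euclidean distances
to a normal and a dysbiotic centroid.  The scorer is pluggable: anything
producing a per-sample real score with L/M/H categories can replace it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import QPCR_TARGETS

DI_CLIP = 10.0
DISTANCE_FLOOR = 1e-6
SCALE_FLOOR = 1e-3


@dataclass
class DIReference:
    """Normal/dysbiotic centroids and per-target scale (log10 units)."""

    centroid_normal: pd.Series
    centroid_dysbiotic: pd.Series
    scale: pd.Series

    def to_dict(self) -> dict:
        return {
            "centroid_normal": self.centroid_normal.to_dict(),
            "centroid_dysbiotic": self.centroid_dysbiotic.to_dict(),
            "scale": self.scale.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DIReference":
        return cls(
            pd.Series(d["centroid_normal"]),
            pd.Series(d["centroid_dysbiotic"]),
            pd.Series(d["scale"]),
        )


def categorize_di(di) -> pd.Series:
    """Trichotomize: L (DI <= 0), M (0 < DI < 2), H (DI >= 2)."""
    di = np.asarray(di, dtype=float)
    cat = np.where(di <= 0, "L", np.where(di < 2, "M", "H"))
    return pd.Series(cat)


class DysbiosisIndex(BaseEstimator, TransformerMixin):
    """Nearest-centroid log-distance-ratio dysbiosis scorer.

    ``fit(panel, labels)`` learns per-target centroids from samples
    labeled "normal"/"dysbiotic" and a pooled per-target SD (floored at
    1e-3); ``transform(panel)`` returns the per-sample DI.
    """

    def __init__(self, min_group: int = 3):
        self.min_group = min_group

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y), index=X.index)
        for label in ("normal", "dysbiotic"):
            if (y == label).sum() < self.min_group:
                raise ValueError(f"need >= {self.min_group} samples labeled {label!r}")
        extra = set(y.unique()) - {"normal", "dysbiotic"}
        if extra:
            raise ValueError(f"unknown label(s): {sorted(extra)}")
        norm = X.loc[y == "normal"]
        dys = X.loc[y == "dysbiotic"]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.centroid_normal_ = norm.mean(axis=0)
        self.centroid_dysbiotic_ = dys.mean(axis=0)
        n1, n2 = len(norm), len(dys)
        pooled_var = ((n1 - 1) * norm.var(ddof=1) + (n2 - 1) * dys.var(ddof=1)) / (n1 + n2 - 2)
        self.scale_ = np.sqrt(pooled_var).clip(lower=SCALE_FLOOR)
        return self

    @property
    def reference_(self) -> DIReference:
        return DIReference(self.centroid_normal_, self.centroid_dysbiotic_, self.scale_)

    def transform(self, X: pd.DataFrame) -> pd.Series:
        return compute_di(X, self.reference_)["di"]


def fit_reference(panel: pd.DataFrame, labels) -> DIReference:
    """Fit normal/dysbiotic centroids and scale from a labeled panel."""
    return DysbiosisIndex().fit(panel, labels).reference_


def compute_di(panel: pd.DataFrame, ref: DIReference) -> pd.DataFrame:
    """Score each sample: DI = ln(d_N/d_D), clipped to [-10, 10].

    Distances are Euclidean on targets divided by the reference scale;
    each distance is floored at 1e-6 so a sample sitting exactly on a
    centroid clips to +/-10 rather than diverging.
    """
    cols = list(ref.centroid_normal.index)
    missing = set(cols) - set(panel.columns)
    if missing:
        raise ValueError(f"panel lacks reference target(s): {sorted(missing)}")
    scale = ref.scale.reindex(cols)
    c_n = (ref.centroid_normal.reindex(cols) / scale).to_numpy()
    c_d = (ref.centroid_dysbiotic.reindex(cols) / scale).to_numpy()
    if np.allclose(c_n, c_d):
        raise ValueError("degenerate reference: centroids coincide")
    x = (panel[cols] / scale).to_numpy(dtype=float)
    d_n = np.maximum(np.linalg.norm(x - c_n, axis=1), DISTANCE_FLOOR)
    d_d = np.maximum(np.linalg.norm(x - c_d, axis=1), DISTANCE_FLOOR)
    di = np.clip(np.log(d_n / d_d), -DI_CLIP, DI_CLIP)
    return pd.DataFrame(
        {"di": di, "category": categorize_di(di).to_numpy()}, index=panel.index
    )


def pearson_table(y: pd.Series, X: pd.DataFrame, y_name: str = "di") -> pd.DataFrame:
    """Pearson r and t-based p of ``y`` against each column of ``X``.

    Pairwise-complete over finite values; zero-variance pairs are
    skipped with a warning.
    """
    rows = []
    for col in X.columns:
        pair = pd.concat([y.rename("y"), X[col].rename("x")], axis=1).dropna()
        if len(pair) < 3:
            warnings.warn(f"{col}: fewer than 3 complete pairs; skipped")
            continue
        if pair["x"].std(ddof=0) == 0 or pair["y"].std(ddof=0) == 0:
            warnings.warn(f"{col}: zero variance; skipped")
            continue
        r, p = stats.pearsonr(pair["y"], pair["x"])
        rows.append({"variable": col, "against": y_name, "r": float(r),
                     "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows, columns=["variable", "against", "r", "p", "n"])


def di_correlations(di: pd.DataFrame, panel: pd.DataFrame,
                    alpha: pd.Series = None) -> pd.DataFrame:
    """DI versus each qPCR target (and Faith's PD when supplied)."""
    ids = panel.index.intersection(di.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 shared samples")
    X = panel.loc[ids, [c for c in QPCR_TARGETS if c in panel.columns]].copy()
    if alpha is not None:
        X["faith_pd"] = alpha.reindex(ids)
    return pearson_table(di.loc[ids, "di"], X, y_name="di")
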