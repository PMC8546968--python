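"""Taxonomic aggregation, normalization, and differential-abundance screening.

The screening chain is the study's: total-sum scaling, square-root
transform, a per-group zero-prevalence filter, Kruskal-Wallis across the
four stages with Benjamini-Hochberg control across features, and Dunn's
post hoc z tests (BH-adjusted within feature across the six group pairs
by default).  The same chain applies to any per-sample numeric table
(bile acids, SCFAs, DI, serum metabolites).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import OtuTable, TAXONOMIC_RANKS

AGGREGATION_RANKS = ("phylum", "class", "order", "family")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def aggregate_taxa(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum OTU counts over the lineage prefix through ``rank``.

    OTUs whose label at ``rank`` is empty are pooled under
    ``unclassified_<parent>``, where parent is the nearest non-empty
    ancestor rank label.
    """
    if rank not in AGGREGATION_RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {AGGREGATION_RANKS}")
    depth = TAXONOMIC_RANKS.index(rank)
    groups = {}
    for otu in table.otu_ids:
        parts = [p.strip() for p in str(table.lineage[otu]).split(";")]
        parts += [""] * (7 - len(parts))
        labels = [p if p not in ("", "k__", "p__", "c__", "o__", "f__", "g__", "s__") else ""
                  for p in parts]
        if labels[depth]:
            key = ";".join(parts[: depth + 1])
        else:
            parent = next((labels[d] for d in range(depth - 1, -1, -1) if labels[d]), "root")
            key = f"unclassified_{parent}"
        groups.setdefault(key, []).append(otu)
    out = pd.DataFrame(
        {key: table.counts[otus].sum(axis=1) for key, otus in groups.items()},
        index=table.counts.index,
    )
    return out


class TssSqrt(BaseEstimator, TransformerMixin):
    """Total-sum scaling followed by a square-root transform.

    Stateless: each sample is divided by its total and square-rooted, so
    squared outputs sum to 1 per sample.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        totals = X.sum(axis=1)
        zero = totals[totals <= 0]
        if len(zero):
            raise ValueError(f"zero-total sample(s): {list(zero.index)[:10]}")
        return np.sqrt(X.div(totals, axis=0))


def tss_sqrt(table: pd.DataFrame) -> pd.DataFrame:
    return TssSqrt().fit_transform(table)


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Drop features that are zero in more than half of every group.

    A feature survives if in at least one group it is non-zero in at
    least half the samples.  Fitted attributes: ``kept_features_``,
    ``dropped_features_``.
    """

    def fit(self, X: pd.DataFrame, y):
        labels = pd.Series(np.asarray(y), index=X.index)
        drop = np.ones(X.shape[1], dtype=bool)
        for g in labels.unique():
            sub = X.loc[labels == g]
            zero_frac = (sub == 0).mean(axis=0).to_numpy()
            drop &= zero_frac > 0.5
        self.kept_features_ = list(X.columns[~drop])
        self.dropped_features_ = list(X.columns[drop])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_features_]


def prevalence_filter(table: pd.DataFrame, labels) -> tuple[pd.DataFrame, list]:
    """Functional wrapper; returns (filtered table, dropped feature ids)."""
    f = PrevalenceFilter().fit(table, labels)
    return f.transform(table), f.dropped_features_


def _kruskal(groups) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _dunn(values: np.ndarray, codes: np.ndarray, n_groups: int) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = np.array([ranks[codes == g].mean() for g in range(n_groups)])
    sizes = np.array([(codes == g).sum() for g in range(n_groups)])
    rows = []
    for i, j in itertools.combinations(range(n_groups), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"i": i, "j": j, "z": float(z), "p": float(min(p, 1.0))})
    return pd.DataFrame(rows)


@dataclass
class DifferentialResult:
    """Kruskal-Wallis screen with Dunn post hoc tests.

    ``features``: per-feature H, p, q (BH across features).
    ``pairwise``: long table of Dunn z/p/q for features passing the q
    threshold.
    """

    features: pd.DataFrame
    pairwise: pd.DataFrame
    alpha_q: float


def kw_dunn_bh(table: pd.DataFrame, labels, alpha_q: float = 0.10,
               dunn_adjust: str = "within") -> DifferentialResult:
    """Kruskal-Wallis + BH across features, Dunn's tests on significant ones.

    Parameters
    ----------
    alpha_q : float
        q threshold gating the post hoc tests (0.10 for taxa, 0.20 for
        the relaxed OTU screen).
    dunn_adjust : {"within", "pooled"}
        BH family for Dunn p values: within each feature across the
        group pairs (default), or pooled over all (feature, pair) cells.
    """
    labels = pd.Series(np.asarray(labels), index=table.index)
    codes, uniques = pd.factorize(labels, sort=True)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least 2 non-empty groups")
    if dunn_adjust not in ("within", "pooled"):
        raise ValueError("dunn_adjust must be 'within' or 'pooled'")

    feats, hs, ps = [], [], []
    mat = table.to_numpy(dtype=float)
    for k, feat in enumerate(table.columns):
        vals = mat[:, k]
        h, p = _kruskal([vals[codes == g] for g in range(n_groups)])
        feats.append(feat)
        hs.append(h)
        ps.append(p)
    features = pd.DataFrame({"feature": feats, "H": hs, "p": ps})
    features["q"] = bh_adjust(features["p"])

    pair_rows = []
    for k, feat in enumerate(table.columns):
        if features["q"].iloc[k] >= alpha_q:
            continue
        dunn = _dunn(mat[:, k], codes, n_groups)
        dunn.insert(0, "feature", feat)
        dunn["group_1"] = [uniques[i] for i in dunn["i"]]
        dunn["group_2"] = [uniques[j] for j in dunn["j"]]
        pair_rows.append(dunn.drop(columns=["i", "j"]))
    if pair_rows:
        pairwise = pd.concat(pair_rows, ignore_index=True)
        if dunn_adjust == "within":
            pairwise["q"] = pairwise.groupby("feature")["p"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        else:
            pairwise["q"] = bh_adjust(pairwise["p"])
        pairwise = pairwise[["feature", "group_1", "group_2", "z", "p", "q"]]
    else:
        pairwise = pd.DataFrame(columns=["feature", "group_1", "group_2", "z", "p", "q"])
    return DifferentialResult(features, pairwise, alpha_q)


def mann_whitney(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``method="asymptotic"`` uses the tie-corrected normal approximation
    (the study's scale); ``"exact"`` enumerates the null distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
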