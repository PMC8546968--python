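"""Alpha and beta diversity at a fixed rarefaction depth.

Alpha diversity is observed species and Faith's phylogenetic diversity
(root-inclusive convention) computed on counts rarefied once, with a
seeded draw, to a fixed depth (default 7,000 reads; samples below depth
are dropped and reported, not scaled).  Beta diversity is Bray-Curtis,
ordinated by classical scaling (PCoA) and tested by one-way PERMANOVA
with the add-one permutation estimator.  ``distance_variance_explained``
is the McArdle-Anderson (adonis-style) share of distance variance
attributable to a single covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .io import OtuTable, ConsistencyError

DEFAULT_RAREFACTION_DEPTH = 7000


def rarefy(counts, depth: int, seed: int) -> np.ndarray:
    """Subsample one count vector without replacement to exactly ``depth``.

    Raises
    ------
    ValueError
        If the vector total is below ``depth`` (table-level rarefaction
        drops such samples instead).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample total {total} below rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(table: OtuTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
                 seed: int = 0) -> tuple[pd.DataFrame, list]:
    """Rarefy every sample; return (rarefied counts, dropped sample ids)."""
    counts = table.counts
    totals = counts.sum(axis=1)
    dropped = list(counts.index[totals < depth])
    kept = counts.loc[totals >= depth]
    rng = np.random.default_rng(seed)
    out = np.empty(kept.shape, dtype=np.int64)
    for i in range(kept.shape[0]):
        row = kept.iloc[i].to_numpy()
        out[i] = row if row.sum() == depth else rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns), dropped


def observed_species(counts) -> int:
    """Number of features with a strictly positive count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def faith_pd(counts, otu_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the union
    of root-to-tip paths over observed tips (root connection included)."""
    counts = np.asarray(counts)
    tips = {t.name for t in tree.tips()}
    observed = [o for o, c in zip(otu_ids, counts) if c > 0]
    missing = sorted(set(observed) - tips)
    if missing:
        raise ConsistencyError(f"observed OTU(s) absent from tree: {missing[:10]}")
    if not observed:
        return 0.0
    return float(_skbio_faith_pd(counts, taxa=list(otu_ids), tree=tree))


def alpha_diversity(rarefied: pd.DataFrame, tree: TreeNode) -> pd.DataFrame:
    """Observed species and Faith's PD per (already rarefied) sample."""
    otu_ids = list(rarefied.columns)
    rows = {
        sid: (observed_species(row), faith_pd(row, otu_ids, tree))
        for sid, row in zip(rarefied.index, rarefied.to_numpy())
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["observed_species", "faith_pd"]).rename_axis("sample_id")


def bray_curtis(rarefied: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix; an all-zero pair has distance 0."""
    if len(rarefied) < 2:
        raise ValueError("need at least 2 samples")
    x = rarefied.to_numpy(dtype=float)
    from scipy.spatial.distance import pdist, squareform

    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # both-empty convention
    return DistanceMatrix(d, ids=list(rarefied.index))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x kept axes (PC1, PC2, ...)
    eigenvalues: np.ndarray          # kept (positive) eigenvalues, descending
    proportion_explained: np.ndarray  # share of the positive-eigenvalue sum


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix.

    Axes with eigenvalue <= 1e-10 are discarded (no negative-eigenvalue
    correction); each axis's sign is fixed so its largest-magnitude
    loading is positive.
    """
    d = dm.data
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10
    eigval_k, eigvec_k = eigval[keep], eigvec[:, keep]
    coords = eigvec_k * np.sqrt(eigval_k)
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigval[eigval > 0].sum()
    prop = eigval_k / pos_sum if pos_sum > 0 else np.zeros_like(eigval_k)
    cols = [f"PC{k+1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        pd.DataFrame(coords, index=list(dm.ids), columns=cols), eigval_k, prop
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, eye_g: np.ndarray,
               sizes: np.ndarray) -> float:
    # sum over groups of (sum of within-group squared distances) / n_g
    u = eye_g[codes]                      # n x g one-hot
    per_group = (u * (d2 @ u)).sum(axis=0)  # full (i,j) double sum per group
    return float((per_group / (2.0 * sizes)).sum())


def permanova(dm: DistanceMatrix, labels, n_perm: int = 9999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA with the add-one permutation p estimator.

    A zero within-group sum of squares yields an infinite pseudo-F that
    is tie-ranked against (possibly also infinite) permuted statistics.
    """
    labels = pd.Series(np.asarray(labels), index=list(dm.ids))
    # canonicalize to sorted sample ids so p is invariant to input order
    order = sorted(dm.ids)
    dm = dm.filter(order)
    labels = labels.loc[order]
    codes, uniques = pd.factorize(labels, sort=True)
    g = len(uniques)
    if g < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError(f"singleton group: {uniques[np.argmin(sizes)]!r}")
    d2 = dm.data ** 2
    n = d2.shape[0]
    eye_g = np.eye(g)
    ss_total = d2.sum() / (2.0 * n)

    def f_stat(c):
        ss_within = _ss_within(d2, c, eye_g, sizes)
        ss_between = ss_total - ss_within
        if ss_within <= 1e-12 * max(ss_total, 1.0):
            return np.inf, (1.0 if ss_total > 0 else 0.0)
        return (ss_between / (g - 1)) / (ss_within / (n - g)), ss_between / ss_total

    f_obs, r2 = f_stat(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = f_stat(rng.permutation(codes))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def pairwise_permanova(dm: DistanceMatrix, labels, n_perm: int = 9999,
                       seed: int = 0, bh_adjust: bool = False) -> pd.DataFrame:
    """PERMANOVA on every group pair; raw p by default, BH optional."""
    labels = pd.Series(np.asarray(labels), index=list(dm.ids))
    groups = sorted(labels.unique())
    rows = []
    for a, b in itertools.combinations(groups, 2):
        ids = list(labels.index[labels.isin([a, b])])
        res = permanova(dm.filter(ids), labels.loc[ids], n_perm=n_perm, seed=seed)
        rows.append({"group_1": a, "group_2": b, "pseudo_f": res.pseudo_f,
                     "r_squared": res.r_squared, "p": res.p_value})
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def anova_tukey(values, labels) -> dict:
    """One-way ANOVA with Tukey HSD post hoc comparisons.

    All-identical values are defined as F = 0, p = 1 (and all pairwise
    adjusted p = 1) so degenerate inputs never fail.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 members")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    if np.ptp(values) == 0:
        pairwise = pd.DataFrame(
            [{"group_1": groups[i], "group_2": groups[j], "p_adj": 1.0} for i, j in pairs]
        )
        return {"F": 0.0, "p": 1.0, "pairwise": pairwise}
    f, p = stats.f_oneway(*samples)
    if not np.isfinite(f):
        p = 0.0
    res = stats.tukey_hsd(*samples)
    pairwise = pd.DataFrame(
        [{"group_1": groups[i], "group_2": groups[j], "p_adj": float(res.pvalue[i, j])}
         for i, j in pairs]
    )
    return {"F": float(f), "p": float(p), "pairwise": pairwise}


def _design_matrix(covariate: pd.Series) -> np.ndarray:
    if covariate.dtype.kind in "OUSb" or isinstance(covariate.dtype, pd.CategoricalDtype):
        codes, uniques = pd.factorize(covariate, sort=True)
        if len(uniques) < 2:
            raise ValueError("categorical covariate needs >= 2 levels")
        x = np.zeros((len(covariate), len(uniques) - 1))
        for k in range(1, len(uniques)):
            x[codes == k, k - 1] = 1.0
    else:
        vals = covariate.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("covariate must be finite")
        if np.ptp(vals) == 0:
            raise ValueError("constant covariate")
        x = vals[:, None]
    return np.column_stack([np.ones(len(covariate)), x])


def distance_variance_explained(dm: DistanceMatrix, covariate, n_perm: int = 999,
                                seed: int = 0) -> dict:
    """Share of distance variance explained by one covariate (adonis-style).

    McArdle-Anderson formulation: Gower-center the squared distances to
    G, project on the intercept+covariate design's hat matrix H, and
    report R^2 = tr(HGH)/tr(G) with a permutation p for the pseudo-F.
    """
    covariate = pd.Series(covariate, index=list(dm.ids)) if not isinstance(covariate, pd.Series) \
        else covariate.loc[list(dm.ids)]
    x = _design_matrix(covariate)
    n = len(dm.ids)
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    rank = np.linalg.matrix_rank(x)
    dfm, dfe = rank - 1, n - rank
    if dfe <= 0:
        raise ValueError("not enough residual degrees of freedom")

    def stat(xmat):
        h = xmat @ np.linalg.pinv(xmat)
        tr_hg = np.trace(h @ g)
        return tr_hg

    tr_g = np.trace(g)
    tr_hg = stat(x)
    r2 = tr_hg / tr_g if tr_g > 0 else 0.0
    denom = tr_g - tr_hg
    f_obs = np.inf if denom <= 0 else (tr_hg / dfm) / (denom / dfe)
    rng = np.random.default_rng(seed)
    count = 0
    rows = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(rows)
        tr_hg_p = stat(x[perm])
        denom_p = tr_g - tr_hg_p
        f_p = np.inf if denom_p <= 0 else (tr_hg_p / dfm) / (denom_p / dfe)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"r_squared": float(r2), "pseudo_f": float(f_obs), "p": float(p)}
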