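"""Diversity operations against hand values and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

from mmvdbiome import diversity as dv
from mmvdbiome.io import ConsistencyError, OtuTable
from mmvdbiome.simulate import simulate_tree


def brute_force_faith_pd(tree, observed_tips):
    """Independent oracle: sum branch lengths over the union of
    root-to-tip paths, walking each observed tip up to the root."""
    edges = set()
    for tip in tree.tips():
        if tip.name not in observed_tips:
            continue
        node = tip
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
    lengths = {id(n): (n.length or 0.0) for n in tree.traverse()}
    return sum(lengths[e] for e in edges)


class TestRarefy:
    def test_identity_at_depth(self):
        v = np.array([3000, 4000])
        np.testing.assert_array_equal(dv.rarefy(v, 7000, seed=1), v)

    def test_below_depth_sample_dropped_and_listed(self):
        counts = pd.DataFrame([[3000, 2000], [4000, 4000]],
                              index=["lo", "hi"], columns=["o1", "o2"])
        rare, dropped = dv.rarefy_table(OtuTable(counts), depth=7000, seed=1)
        assert dropped == ["lo"]
        assert list(rare.index) == ["hi"]

    def test_conservation_and_bounds(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            v = rng.integers(0, 500, size=30)
            v[0] += 3000  # guarantee enough depth
            out = dv.rarefy(v, 2000, seed=seed)
            assert out.sum() == 2000
            assert (out <= v).all() and (out >= 0).all()

    def test_seeded_reproducibility(self):
        v = np.arange(1, 50) * 10
        np.testing.assert_array_equal(dv.rarefy(v, 5000, seed=3),
                                      dv.rarefy(v, 5000, seed=3))


class TestAlpha:
    @pytest.mark.parametrize("counts,expected", [([0, 3, 1, 0], 2), ([0, 0], 0), ([7], 1)])
    def test_observed_species(self, counts, expected):
        assert dv.observed_species(counts) == expected

    @pytest.mark.parametrize("observed,expected", [
        (["A", "B"], 4.0), (["C"], 4.0), (["A", "B", "C"], 8.0)])
    def test_faith_pd_hand_tree(self, hand_tree, observed, expected):
        counts = [1 if t in observed else 0 for t in ["A", "B", "C"]]
        assert dv.faith_pd(counts, ["A", "B", "C"], hand_tree) == pytest.approx(expected)

    def test_faith_pd_missing_tip_rejected(self, hand_tree):
        with pytest.raises(ConsistencyError, match="Z"):
            dv.faith_pd([1], ["Z"], hand_tree)

    def test_faith_pd_matches_brute_force_oracle(self):
        """Exact agreement with the path-union oracle on 100 random
        (tree <= 20 tips, community) instances."""
        rng = np.random.default_rng(42)
        for i in range(100):
            n = int(rng.integers(2, 21))
            tree = simulate_tree(n, seed=1000 + i)
            tips = sorted(t.name for t in tree.tips())
            counts = rng.integers(0, 3, size=n)
            if counts.sum() == 0:
                counts[0] = 1
            observed = {t for t, c in zip(tips, counts) if c > 0}
            assert dv.faith_pd(counts, tips, tree) == pytest.approx(
                brute_force_faith_pd(tree, observed), abs=1e-12)


class TestBrayCurtis:
    def test_hand_values(self):
        df = pd.DataFrame([[2, 0], [0, 5], [1, 1], [1, 3]],
                          index=list("abcd"), columns=["o1", "o2"])
        dm = dv.bray_curtis(df)
        assert dm["a", "a"] == 0.0
        assert dm["a", "b"] == pytest.approx(1.0)  # disjoint support
        assert dm["c", "d"] == pytest.approx(2 / 6)

    def test_both_empty_pair_convention(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"), columns=["o1", "o2"])
        dm = dv.bray_curtis(df)
        assert dm["a", "b"] == 0.0

    def test_bounded_in_unit_interval(self, cohort_analysis):
        dm = dv.bray_curtis(cohort_analysis["rarefied"])
        assert dm.data.min() >= 0.0 and dm.data.max() <= 1.0


class TestPcoa:
    def test_collinear_recovery(self):
        pos = np.array([0.0, 1.0, 3.0])
        d = np.abs(pos[:, None] - pos[None, :])
        res = dv.pcoa(DistanceMatrix(d, ids=list("abc")))
        assert len(res.eigenvalues) == 1
        pc1 = res.coordinates["PC1"].to_numpy()
        gaps = np.abs(np.diff(pc1))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0], atol=1e-10)

    def test_zero_matrix(self):
        res = dv.pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))
        assert res.coordinates.shape[1] == 0

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 4))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        res = dv.pcoa(DistanceMatrix(d, ids=[str(i) for i in range(12)]))
        coords = res.coordinates.to_numpy()
        d_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(d_hat, d, atol=1e-8)

    def test_proportions_normalized_and_sorted(self, cohort_analysis):
        dm = dv.bray_curtis(cohort_analysis["rarefied"])
        res = dv.pcoa(dm)
        assert res.proportion_explained.sum() <= 1.0 + 1e-12
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        res = dv.pcoa(DistanceMatrix(d, ids=list("abcdef")))
        for k in range(res.coordinates.shape[1]):
            col = res.coordinates.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        data = np.asarray(dm.data)
        data.setflags(write=True)
        data[0, 1] = 2.0  # sneak in asymmetry past the container
        with pytest.raises(ValueError, match="symmetric"):
            dv.pcoa(dm)


def _exhaustive_permanova_p(d, labels):
    """Enumerate every relabeling with the observed group sizes."""
    dm = DistanceMatrix(d, ids=[str(i) for i in range(len(labels))])
    obs = dv.permanova(dm, labels, n_perm=1, seed=0).pseudo_f
    n = len(labels)
    k = sum(1 for l in labels if l == labels[0])
    count = total = 0
    for combo in itertools.combinations(range(n), k):
        perm = np.array(["y"] * n, dtype=object)
        perm[list(combo)] = "x"
        f = dv.permanova(dm, perm, n_perm=1, seed=0).pseudo_f
        total += 1
        if f >= obs - 1e-12:
            count += 1
    return count / total


@pytest.fixture(scope="module")
def six_sample_dm():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(6, 3))
    x[:3] += 1.0
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    return d, ["x", "x", "x", "y", "y", "y"]


class TestPermanova:
    def test_matches_exhaustive_enumeration(self, six_sample_dm):
        d, labels = six_sample_dm
        p_exact = _exhaustive_permanova_p(d, labels)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        p_mc = dv.permanova(dm, labels, n_perm=9999, seed=3).p_value
        assert p_mc == pytest.approx(p_exact, abs=3 * np.sqrt(p_exact * (1 - p_exact) / 9999) + 1e-4)

    def test_matches_skbio(self, six_sample_dm):
        """Cross-check pseudo-F against the independent scikit-bio
        implementation."""
        from skbio.stats.distance import permanova as skbio_permanova

        d, labels = six_sample_dm
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        ours = dv.permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=np.array(labels), permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_no_effect_case(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 3))
        x2 = np.vstack([x, x])  # duplicate rows: two identical groups
        d = np.linalg.norm(x2[:, None] - x2[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        res = dv.permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=0)
        assert abs(res.r_squared) < 0.05
        assert res.p_value > 0.5

    def test_invariance_to_relabeling_and_reordering(self, six_sample_dm):
        d, labels = six_sample_dm
        ids = [str(i) for i in range(6)]
        dm = DistanceMatrix(d, ids=ids)
        base = dv.permanova(dm, labels, n_perm=499, seed=5)
        renamed = dv.permanova(dm, ["g2" if l == "x" else "g1" for l in labels],
                               n_perm=499, seed=5)
        assert renamed.p_value == base.p_value
        order = [3, 1, 5, 0, 2, 4]
        dm2 = dm.filter([ids[i] for i in order])
        res2 = dv.permanova(dm2, [labels[i] for i in order], n_perm=499, seed=5)
        assert res2.p_value == base.p_value
        assert res2.pseudo_f == pytest.approx(base.pseudo_f, rel=1e-12)

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ValueError, match="singleton"):
            dv.permanova(dm, ["a", "a", "b"], n_perm=9)

    def test_p_floor(self, six_sample_dm):
        d, labels = six_sample_dm
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = dv.permanova(dm, labels, n_perm=99, seed=0)
        assert res.p_value >= 1 / (99 + 1)


class TestAnovaTukey:
    def test_identical_groups(self):
        res = dv.anova_tukey([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_all_values_identical(self):
        res = dv.anova_tukey([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res["F"] == 0.0 and res["p"] == 1.0
        assert (res["pairwise"]["p_adj"] == 1.0).all()

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        res = dv.anova_tukey(np.concatenate([x, y]), ["a"] * 10 + ["b"] * 12)
        t, p_t = stats.ttest_ind(x, y)
        assert res["F"] == pytest.approx(t ** 2, rel=1e-10)
        assert res["p"] == pytest.approx(p_t, rel=1e-10)

    def test_strong_separation(self):
        res = dv.anova_tukey([0, 0.1, 10, 10.1], ["a", "a", "b", "b"])
        assert res["p"] < 0.001


class TestDistanceVarianceExplained:
    def test_equals_permanova_r2_for_categorical(self, six_sample_dm=None):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(12, 3))
        x[:6] += 0.8
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        ids = [str(i) for i in range(12)]
        dm = DistanceMatrix(d, ids=ids)
        labels = ["a"] * 6 + ["b"] * 6
        r2_perm = dv.permanova(dm, labels, n_perm=9, seed=0).r_squared
        res = dv.distance_variance_explained(dm, pd.Series(labels, index=ids), n_perm=9)
        assert res["r_squared"] == pytest.approx(r2_perm, abs=1e-10)

    def test_distance_built_from_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        d = np.abs(x[:, None] - x[None, :])
        ids = [str(i) for i in range(20)]
        res = dv.distance_variance_explained(
            DistanceMatrix(d, ids=ids), pd.Series(x, index=ids), n_perm=99, seed=0)
        assert res["r_squared"] > 0.9
        assert res["p"] <= 0.05

    def test_constant_covariate_rejected(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            dv.distance_variance_explained(dm, pd.Series([1.0] * 4, index=list("abcd")))
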