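import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import spearmanr

from tagpipe.diversity import (
    PCoACoordinates,
    bray_curtis,
    pcoa,
    procrustes,
    rarefaction_curve,
    unifrac,
)
from tagpipe.otu import OTUTable


def table_from(cols, index=None):
    df = pd.DataFrame(cols)
    if index is not None:
        df.index = index
    return OTUTable(counts=df)


# ---------------------------------------------------------------- rarefaction

class TestRarefactionCurve:
    def test_full_depth_equals_raw_observed(self):
        t = table_from({"s": [5, 0, 3, 2]})
        df = rarefaction_curve(t, depths=[10], reps=5, seed=1)
        assert df.loc[0, "mean_observed_otus"] == 3.0
        assert df.loc[0, "sd_observed_otus"] == 0.0

    def test_depth_one_gives_one_otu(self):
        t = table_from({"s": [5, 3, 2]})
        df = rarefaction_curve(t, depths=[1], reps=10, seed=1)
        assert df.loc[0, "mean_observed_otus"] == 1.0

    def test_matches_closed_form_hypergeometric_expectation(self):
        from scipy.special import comb

        col = np.array([40, 25, 10, 4, 1])
        N = col.sum()
        d = 30
        # closed form: E[observed] = sum_k 1 - C(N - n_k, d) / C(N, d)
        expected = sum(1 - comb(N - nk, d) / comb(N, d) for nk in col)
        t = table_from({"s": col})
        reps = 400
        df = rarefaction_curve(t, depths=[d], reps=reps, seed=3)
        mean = df.loc[0, "mean_observed_otus"]
        sd = df.loc[0, "sd_observed_otus"]
        assert abs(mean - expected) <= 3 * sd / np.sqrt(reps) + 1e-9

    def test_excessive_depth_warns_and_skips(self):
        t = table_from({"s": [2, 1]})
        with pytest.warns(UserWarning, match="exceeds"):
            df = rarefaction_curve(t, depths=[100], reps=2, seed=1)
        assert df.empty

    def test_observed_otus_nondecreasing_in_depth(self):
        rng = np.random.default_rng(8)
        t = table_from({"s": rng.integers(0, 40, 25)})
        depths = [5, 20, 80, 200, int(t.counts["s"].sum())]
        df = rarefaction_curve(t, depths=depths, reps=20, seed=4)
        means = df["mean_observed_otus"].to_numpy()
        assert (np.diff(means) >= -1e-9).all()


# ---------------------------------------------------------------- bray-curtis

class TestBrayCurtis:
    def test_identical_columns_zero(self):
        dm = bray_curtis(table_from({"a": [3, 1], "b": [3, 1]}))
        assert dm["a", "b"] == 0.0

    def test_disjoint_columns_one(self):
        dm = bray_curtis(table_from({"a": [4, 0], "b": [0, 4]}))
        assert dm["a", "b"] == 1.0

    def test_hand_arithmetic(self):
        dm = bray_curtis(table_from({"a": [6, 2], "b": [2, 2]}))
        assert dm["a", "b"] == pytest.approx(4 / 12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 50, size=(12, 5))
        t = table_from({f"s{i}": counts[:, i] for i in range(5)})
        dm = bray_curtis(t)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = scipy_braycurtis(counts[:, i], counts[:, j])
                assert dm[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_pair_warns_zero(self):
        with pytest.warns(UserWarning):
            dm = bray_curtis(table_from({"a": [0, 0], "b": [0, 0]}))
        assert dm["a", "b"] == 0.0


# -------------------------------------------------------------------- unifrac

def oracle_unifrac(newick, otu_ids, counts, weighted, normalized=True):
    """Independent per-branch enumeration using dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    count_a = dict(zip(otu_ids, counts[:, 0]))
    count_b = dict(zip(otu_ids, counts[:, 1]))
    ta, tb = counts[:, 0].sum(), counts[:, 1].sum()
    num = 0.0
    den = 0.0
    shared_or = 0.0
    unique = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        length = edge.length or 0.0
        tips = {
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        }
        ca = sum(count_a.get(o, 0) for o in otu_ids if o in tips)
        cb = sum(count_b.get(o, 0) for o in otu_ids if o in tips)
        if weighted:
            pa, pb = ca / ta, cb / tb
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        else:
            if (ca > 0) != (cb > 0):
                unique += length
            if ca > 0 or cb > 0:
                shared_or += length
    if weighted:
        return num / den if (normalized and den) else num
    return unique / shared_or if shared_or else 0.0


def random_binary_newick(rng, labels):
    nodes = [f"{l}:{rng.uniform(0.1, 1.0):.4f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.4f}")
    return f"({nodes[0]});"


class TestUnifrac:
    def test_identical_communities_zero_both_variants(self):
        tree = "((t1:1,t2:2):0.5,(t3:1,t4:1):0.5);"
        t = table_from({"a": [3, 1, 2, 5], "b": [3, 1, 2, 5]},
                       index=["t1", "t2", "t3", "t4"])
        for weighted in (False, True):
            dm = unifrac(t, tree, weighted=weighted)
            assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_two_tip_tree_unweighted_one(self):
        tree = "(t1:1,t2:1);"
        t = table_from({"a": [4, 0], "b": [0, 4]}, index=["t1", "t2"])
        dm = unifrac(t, tree, weighted=False)
        assert dm["a", "b"] == 1.0

    def test_four_tip_hand_computation(self):
        # tree: ((t1:1,t2:2):1,(t3:3,t4:1):2);
        # A = {t1:2, t3:1}, B = {t2:1, t3:1}
        tree = "((t1:1,t2:2):1,(t3:3,t4:1):2);"
        t = table_from({"A": [2, 0, 1, 0], "B": [0, 1, 1, 0]},
                       index=["t1", "t2", "t3", "t4"])
        # unweighted by hand:
        # unique branches: t1 (1, A only), t2 (2, B only); shared: inner-left
        # (1, both), t3 (3, both), inner-right (2, both)
        # -> unique = 3, either = 1+2+1+3+2 = 9
        dm = unifrac(t, tree, weighted=False)
        assert dm["A", "B"] == pytest.approx(3 / 9)
        # weighted (normalized) by hand: pA = (2/3, 0, 1/3), pB = (0, 1/2, 1/2)
        # per branch l*|dp|: t1 1*2/3, t2 2*1/2, innerL 1*|2/3-1/2|,
        # t3 3*|1/3-1/2|, innerR 2*|1/3-1/2|, t4 0
        num = 1 * 2 / 3 + 2 * 1 / 2 + 1 * abs(2 / 3 - 1 / 2) + 3 * (1 / 6) + 2 * (1 / 6)
        den = (1 * 2 / 3 + 2 * 1 / 2 + 1 * (2 / 3 + 1 / 2)
               + 3 * (1 / 3 + 1 / 2) + 2 * (1 / 3 + 1 / 2))
        dmw = unifrac(t, tree, weighted=True, normalized=True)
        assert dmw["A", "B"] == pytest.approx(num / den, abs=1e-12)

    def test_unmapped_otu_raises_with_names(self):
        tree = "(t1:1,t2:1);"
        t = table_from({"a": [1, 1]}, index=["t1", "missing"])
        with pytest.raises(ValueError, match="missing"):
            unifrac(t, tree)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_agrees_with_brute_force_on_random_8_tip_instances(self, weighted):
        rng = np.random.default_rng(17)
        labels = [f"t{i}" for i in range(1, 9)]
        for _ in range(100):
            newick = random_binary_newick(rng, labels)
            counts = rng.integers(0, 8, size=(8, 2))
            if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
                continue
            t = table_from({"a": counts[:, 0], "b": counts[:, 1]},
                           index=labels)
            dm = unifrac(t, newick, weighted=weighted)
            expected = oracle_unifrac(newick, labels, counts, weighted)
            assert dm["a", "b"] == pytest.approx(expected, abs=1e-9)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(23)
        labels = [f"t{i}" for i in range(1, 9)]
        newick = random_binary_newick(rng, labels)
        t = table_from(
            {f"s{i}": rng.integers(1, 9, size=8) for i in range(4)},
            index=labels,
        )
        for weighted in (False, True):
            dm = unifrac(t, newick, weighted=weighted)
            assert np.allclose(dm.data, dm.data.T)
            assert (np.diag(dm.data) == 0).all()
            assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()


# ----------------------------------------------------------------------- pcoa

class TestPCoA:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        from skbio.stats.distance import DistanceMatrix

        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=["a", "b", "c"]))
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_roundtrip_of_planar_points(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix

        rng = np.random.default_rng(31)
        pts = rng.normal(size=(7, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(7)])
        res = pcoa(dm)
        recovered = squareform(pdist(res.coords))
        np.testing.assert_allclose(recovered, dm.data, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        from skbio.stats.distance import DistanceMatrix

        d = np.array(
            [[0, 0, 2.0], [0, 0, 2.0], [2.0, 2.0, 0]], dtype=float
        )
        res = pcoa(DistanceMatrix(d, ids=["a", "a2", "b"]))
        np.testing.assert_allclose(res.coords[0], res.coords[1], atol=1e-9)

    def test_axes_ordered_by_decreasing_eigenvalue(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix

        rng = np.random.default_rng(37)
        pts = rng.normal(size=(9, 4)) * np.array([5, 2, 1, 0.2])
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(9)])
        res = pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()


# ----------------------------------------------------------------- procrustes

def config(labels, coords):
    coords = np.asarray(coords, dtype=float)
    return PCoACoordinates(labels=list(labels), coords=coords,
                           eigenvalues=np.ones(coords.shape[1]))


def rotation(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


class TestProcrustes:
    def test_rigid_motion_and_scaling_gives_zero_m2(self):
        rng = np.random.default_rng(41)
        labels = [f"s{i}" for i in range(10)]
        a = rng.normal(size=(10, 2))
        b = 3.7 * a @ rotation(0.83).T + np.array([5.0, -2.0])
        res = procrustes(config(labels, a), config(labels, b),
                         n_permutations=99, seed=1)
        assert res.m2 <= 1e-12
        assert res.p_value >= 1 / 100

    def test_m2_invariant_to_rigid_motion_of_either_input(self):
        rng = np.random.default_rng(43)
        labels = [f"s{i}" for i in range(8)]
        a = rng.normal(size=(8, 2))
        b = rng.normal(size=(8, 2))
        base = procrustes(config(labels, a), config(labels, b), 9, seed=1).m2
        b2 = 0.5 * b @ rotation(1.2).T + 7
        again = procrustes(config(labels, a), config(labels, b2), 9, seed=1).m2
        assert again == pytest.approx(base, abs=1e-9)

    def test_label_mismatch_and_too_few_samples(self):
        a = config(["a", "b", "c"], np.eye(3))
        with pytest.raises(ValueError, match="label"):
            procrustes(a, config(["a", "b", "x"], np.eye(3)), 9)
        small = config(["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="3"):
            procrustes(small, small, 9)

    def test_matching_by_label_not_order(self):
        rng = np.random.default_rng(47)
        labels = [f"s{i}" for i in range(6)]
        a = rng.normal(size=(6, 2))
        perm = rng.permutation(6)
        b = config([labels[i] for i in perm], a[perm])
        res = procrustes(config(labels, a), b, 99, seed=1)
        assert res.m2 <= 1e-12

    def test_m2_monotone_in_noise(self):
        rng = np.random.default_rng(53)
        labels = [f"s{i}" for i in range(12)]
        a = rng.normal(size=(12, 3))
        noise = rng.normal(size=(12, 3))
        amplitudes = [0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6]
        m2s = [
            procrustes(config(labels, a), config(labels, a + amp * noise),
                       9, seed=1).m2
            for amp in amplitudes
        ]
        rho, _ = spearmanr(amplitudes, m2s)
        assert rho > 0

    def test_p_value_floor(self):
        rng = np.random.default_rng(59)
        labels = [f"s{i}" for i in range(10)]
        a = rng.normal(size=(10, 2))
        res = procrustes(config(labels, a), config(labels, a), 999, seed=2)
        assert res.p_value >= 1 / 1000

    def test_null_p_values_roughly_uniform_small(self):
        # light version; the 200-null/999-perm check is in the acceptance suite
        rng = np.random.default_rng(61)
        labels = [f"s{i}" for i in range(10)]
        rejections = 0
        n_sims = 40
        for _ in range(n_sims):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            res = procrustes(config(labels, a), config(labels, b), 199,
                             seed=int(rng.integers(1 << 31)))
            if res.p_value <= 0.05:
                rejections += 1
        assert rejections <= 8  # ~2 expected; generous bound


# -------------------------------------------------------- headline property

def test_weighted_unifrac_most_sensitive_to_multiplicative_bias():
    """Two 'primer' datasets derived from one community truth by different
    per-taxon multiplicative bias vectors: the weighted-UniFrac ordination
    shifts more than Bray-Curtis or unweighted-UniFrac ordinations."""
    rng = np.random.default_rng(71)
    n_taxa, n_samples = 30, 8
    labels = [f"t{i}" for i in range(1, n_taxa + 1)]
    newick = random_binary_newick(rng, labels)
    truth = rng.gamma(0.8, size=(n_taxa, n_samples)) * 400
    bias1 = rng.lognormal(0, 1.0, size=n_taxa)
    bias2 = rng.lognormal(0, 1.0, size=n_taxa)

    results = {}
    tables = []
    for bias in (bias1, bias2):
        counts = np.rint(truth * bias[:, None]).astype(int)
        tables.append(table_from(
            {f"s{j}": counts[:, j] for j in range(n_samples)}, index=labels
        ))
    for metric in ("bray", "uu", "wu"):
        dms = []
        for t in tables:
            if metric == "bray":
                dms.append(bray_curtis(t))
            else:
                dms.append(unifrac(t, newick, weighted=(metric == "wu")))
        res = procrustes(pcoa(dms[0]), pcoa(dms[1]), 99, seed=5)
        results[metric] = res.m2
    assert results["wu"] > results["bray"]
    assert results["wu"] > results["uu"]
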