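import itertools

import numpy as np
import pytest

from mcpdiv.diversity import (
    DistanceMatrix,
    TreeNode,
    build_tree,
    goods_coverage,
    parse_newick,
    pcoa,
    rarefaction_curve,
    sample_upgma_with_jackknife,
    unifrac,
)
from mcpdiv.diversity import _upgma_from_distance, _nj_from_distance
from mcpdiv.otu_cluster import OtuTable
from mcpdiv.seqio import SequenceRecord


# ---------------------------------------------------------------------------
# oracles


def _enumerate_expected_richness(counts, n):
    """Brute force: average observed OTUs over all C(N, n) subsets."""
    pool = [i for i, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(pool)), n))
    total = sum(len({pool[i] for i in idx}) for idx in subsets)
    return total / len(subsets)


def _unifrac_oracle(tree, table, weighted):
    """Branch-by-branch enumeration, independent of the vectorized path."""
    branches = []  # (length, set of otu ids below)

    def collect(node, is_root):
        below = set()
        if node.is_leaf:
            below.add(node.name)
        for c in node.children:
            below |= collect(c, False)
        if not is_root:
            branches.append((node.length, frozenset(below)))
        return below

    collect(tree, True)
    out = np.zeros((table.n_samples, table.n_samples))
    totals = table.counts.sum(axis=1)
    depths = tree.leaf_depths()
    for i in range(table.n_samples):
        for j in range(table.n_samples):
            if i == j:
                continue
            a = {o: c for o, c in zip(table.otu_ids, table.counts[i]) if c}
            b = {o: c for o, c in zip(table.otu_ids, table.counts[j]) if c}
            if weighted:
                num = 0.0
                for length, below in branches:
                    pa = sum(a.get(o, 0) for o in below) / totals[i]
                    pb = sum(b.get(o, 0) for o in below) / totals[j]
                    num += length * abs(pa - pb)
                denom = sum(
                    depths[o] * (a.get(o, 0) / totals[i] + b.get(o, 0) / totals[j])
                    for o in table.otu_ids
                )
                out[i, j] = num / denom if denom else 0.0
            else:
                unique = union = 0.0
                for length, below in branches:
                    ina = any(o in a for o in below)
                    inb = any(o in b for o in below)
                    if ina or inb:
                        union += length
                        if ina != inb:
                            unique += length
                out[i, j] = unique / union if union else 0.0
    return out


def _random_table_and_tree(rng, n_leaves, n_samples):
    labels = [f"O{k}" for k in range(n_leaves)]
    d = rng.random((n_leaves, n_leaves))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    tree = _upgma_from_distance(DistanceMatrix(labels, d))
    counts = rng.integers(0, 6, size=(n_samples, n_leaves))
    counts[:, 0] += 1  # no empty sample
    table = OtuTable(
        otu_ids=labels,
        sample_ids=[f"s{k}" for k in range(n_samples)],
        counts=counts,
        representatives={o: SequenceRecord(o, "ACGT") for o in labels},
        threshold=0.9,
    )
    return table, tree


# ---------------------------------------------------------------------------
# rarefaction & coverage


class TestRarefaction:
    def test_two_by_two_closed_form(self):
        res = rarefaction_curve([2, 2], [2])[0]
        assert res.observed_otus == pytest.approx(5 / 3)

    @pytest.mark.parametrize(
        "counts", [[2, 2], [5, 3, 1], [4, 4, 2, 1], [1, 1, 1], [7, 2, 1, 1]]
    )
    def test_exact_matches_subset_enumeration(self, counts):
        for n in (1, 2, min(4, sum(counts))):
            exact = rarefaction_curve(counts, [n])[0].observed_otus
            assert exact == pytest.approx(_enumerate_expected_richness(counts, n))

    def test_full_depth_is_observed_richness(self):
        counts = [5, 3, 1, 1]
        res = rarefaction_curve(counts, [10])[0]
        assert res.observed_otus == pytest.approx(4)

    def test_montecarlo_within_three_se_of_exact(self):
        counts = [6, 4, 2, 1, 1]
        reps = 3000
        mc_draws = []
        rng = np.random.default_rng(0)
        for _ in range(reps):
            sub = rng.multivariate_hypergeometric(np.array(counts), 6)
            mc_draws.append(np.count_nonzero(sub))
        se = np.std(mc_draws, ddof=1) / np.sqrt(reps)
        mc = rarefaction_curve(counts, [6], mode="montecarlo", reps=reps, seed=1)[0]
        exact = rarefaction_curve(counts, [6])[0]
        assert abs(mc.observed_otus - exact.observed_otus) < 3 * se

    def test_depth_exceeding_total_is_error(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 2], [5])

    def test_monotone_and_concave(self, rng):
        """Expected richness rises with depth with diminishing returns."""
        counts = rng.integers(1, 50, size=30)
        depths = list(range(1, int(counts.sum()), 7))
        curve = [r.observed_otus for r in rarefaction_curve(counts, depths)]
        diffs = np.diff(curve)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_large_scale_stability(self):
        """Log-gamma arithmetic holds up at deep-sequencing scale (~1e5)."""
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 2000, size=500)
        res = rarefaction_curve(counts, [int(counts.sum() * 0.5)])[0]
        assert 0 < res.observed_otus <= 500
        assert np.isfinite(res.goods_coverage)


class TestGoodsCoverage:
    def test_closed_form(self):
        assert goods_coverage([5, 3, 1, 1]) == pytest.approx(0.8)

    def test_no_singletons(self):
        assert goods_coverage([5, 3, 2]) == 1.0

    def test_all_singletons(self):
        assert goods_coverage([1, 1, 1]) == 0.0

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            goods_coverage([5, 3], depth=0)
        with pytest.raises(ValueError):
            goods_coverage([5, 3], depth=100)

    def test_coverage_increases_with_depth(self):
        """Deeper subsampling gives higher expected coverage on a fixed
        community — the sequencing-depth gradient."""
        rng = np.random.default_rng(8)
        counts = np.concatenate([rng.integers(1, 4, 60), rng.integers(20, 90, 15)])
        depths = [20, 100, 400, int(counts.sum())]
        values = [goods_coverage(counts, d) for d in depths]
        assert values == sorted(values)


# ---------------------------------------------------------------------------
# trees


class TestTrees:
    def test_upgma_three_leaf_hand_case(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        )
        tree = _upgma_from_distance(dm)
        depths = tree.leaf_depths()
        assert depths == pytest.approx({"A": 0.2, "B": 0.2, "C": 0.2})
        # A and B join first at height 0.1
        cherry = [c for c in tree.children if not c.is_leaf][0]
        assert {leaf.name for leaf in cherry.leaves()} == {"A", "B"}
        assert cherry.leaves()[0].length == pytest.approx(0.1)

    def test_upgma_ultrametric_on_random_inputs(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 9))
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = _upgma_from_distance(DistanceMatrix([f"L{i}" for i in range(n)], d))
            depths = np.array(list(tree.leaf_depths().values()))
            assert np.allclose(depths, depths[0], atol=1e-9)

    def test_identical_sequences_zero_cherry(self):
        reps = [
            SequenceRecord("a", "ACGTACGTACGT"),
            SequenceRecord("b", "ACGTACGTACGT"),
            SequenceRecord("c", "TTTTGGGGCCCC"),
        ]
        tree = build_tree(reps)
        depths = tree.leaf_depths()
        pair_height = [n for n in tree.postorder() if not n.is_leaf and n is not tree]
        assert depths["a"] == pytest.approx(depths["b"])
        cherry = [
            n for n in pair_height if {l.name for l in n.leaves()} == {"a", "b"}
        ][0]
        assert all(leaf.length == pytest.approx(0.0) for leaf in cherry.leaves())

    def test_duplicate_labels_rejected(self):
        reps = [SequenceRecord("a", "ACGT"), SequenceRecord("a", "AAAA")]
        with pytest.raises(ValueError):
            build_tree(reps)

    def test_nj_recovers_additive_distances(self):
        # additive (tree) metric on 4 taxa
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0, 0.3, 0.7, 0.8],
                [0.3, 0, 0.6, 0.7],
                [0.7, 0.6, 0, 0.5],
                [0.8, 0.7, 0.5, 0],
            ]
        )
        tree = _nj_from_distance(DistanceMatrix(labels, d))
        # pairwise path lengths in the tree reproduce the input metric
        paths = {}

        def walk(node, acc, seen):
            acc = acc + node.length
            if node.is_leaf:
                paths[node.name] = acc + 0 * len(seen)
            for c in node.children:
                walk(c, acc, seen)

        # distance via leaf depths + LCA on the rooted tree
        def leafdist(x, y):
            def path_to(node, target, trail):
                if node.name == target and node.is_leaf:
                    return trail + [node]
                for c in node.children:
                    found = path_to(c, target, trail + [node])
                    if found:
                        return found
                return None

            px, py = path_to(tree, x, []), path_to(tree, y, [])
            shared = 0
            for nx, ny in zip(px, py):
                if nx is ny:
                    shared += 1
                else:
                    break
            dist = sum(n.length for n in px[shared:]) + sum(
                n.length for n in py[shared:]
            )
            return dist

        for i, x in enumerate(labels):
            for y in labels[i + 1 :]:
                assert leafdist(x, y) == pytest.approx(d[labels.index(x), labels.index(y)], abs=1e-9)

    def test_newick_round_trip(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        )
        tree = _upgma_from_distance(dm)
        back = parse_newick(tree.to_newick())
        assert sorted(back.leaf_names()) == ["A", "B", "C"]
        assert back.leaf_depths() == pytest.approx(tree.leaf_depths())


# ---------------------------------------------------------------------------
# UniFrac


def _toy_table():
    return OtuTable(
        otu_ids=["X", "Y"],
        sample_ids=["s1", "s2"],
        counts=np.array([[5, 0], [0, 7]]),
        representatives={o: SequenceRecord(o, "ACGT") for o in "XY"},
        threshold=0.9,
    )


class TestUnifrac:
    def test_two_leaf_star_hand_values(self):
        tree = TreeNode(children=[TreeNode("X", 1.0), TreeNode("Y", 1.0)])
        table = _toy_table()
        assert unifrac(table, tree, weighted=False)[("s1", "s2")] == pytest.approx(1.0)
        assert unifrac(table, tree, weighted=True, normalized=False)[
            ("s1", "s2")
        ] == pytest.approx(2.0)
        assert unifrac(table, tree, weighted=True, normalized=True)[
            ("s1", "s2")
        ] == pytest.approx(1.0)

    def test_identical_communities_zero(self):
        tree = TreeNode(children=[TreeNode("X", 1.0), TreeNode("Y", 2.0)])
        table = OtuTable(
            otu_ids=["X", "Y"],
            sample_ids=["s1", "s2"],
            counts=np.array([[3, 6], [1, 2]]),
            representatives={o: SequenceRecord(o, "ACGT") for o in "XY"},
            threshold=0.9,
        )
        for weighted in (False, True):
            assert unifrac(table, tree, weighted=weighted)[("s1", "s2")] == pytest.approx(0.0)

    def test_matches_branch_enumeration_oracle(self, rng):
        """Random small instances agree with a brute-force branch walk."""
        for _ in range(6):
            table, tree = _random_table_and_tree(
                rng, n_leaves=int(rng.integers(3, 9)), n_samples=int(rng.integers(2, 5))
            )
            for weighted in (False, True):
                ours = unifrac(table, tree, weighted=weighted).data
                oracle = _unifrac_oracle(tree, table, weighted)
                assert np.allclose(ours, oracle, atol=1e-12)

    def test_matches_scikit_bio(self):
        """Independent published implementation agrees on a toy instance."""
        import skbio
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(5)
        table, tree = _random_table_and_tree(rng, n_leaves=6, n_samples=3)
        sk_tree = skbio.TreeNode.read([tree.to_newick()])
        sk_tree.length = None
        counts = table.counts
        uw = beta_diversity(
            "unweighted_unifrac", counts, ids=table.sample_ids,
            taxa=table.otu_ids, tree=sk_tree,
        )
        assert np.allclose(unifrac(table, tree, weighted=False).data, uw.data, atol=1e-10)
        w = beta_diversity(
            "weighted_unifrac", counts, ids=table.sample_ids,
            taxa=table.otu_ids, tree=sk_tree, normalized=True,
        )
        assert np.allclose(
            unifrac(table, tree, weighted=True, normalized=True).data, w.data, atol=1e-10
        )

    def test_bounded_symmetric_and_relabel_invariant(self, rng):
        table, tree = _random_table_and_tree(rng, n_leaves=6, n_samples=4)
        for weighted in (False, True):
            dm = unifrac(table, tree, weighted=weighted)
            assert (dm.data >= -1e-12).all() and (dm.data <= 1 + 1e-12).all()
            assert np.allclose(dm.data, dm.data.T)
        # consistent relabeling of OTUs leaves distances unchanged
        mapping = {o: f"Z{k}" for k, o in enumerate(table.otu_ids)}
        for node in tree.postorder():
            if node.is_leaf:
                node.name = mapping[node.name]
        table2 = OtuTable(
            otu_ids=[mapping[o] for o in table.otu_ids],
            sample_ids=table.sample_ids,
            counts=table.counts,
            representatives={
                mapping[o]: table.representatives[o] for o in table.otu_ids
            },
            threshold=0.9,
        )
        assert np.allclose(
            unifrac(table2, tree, weighted=False).data,
            _unifrac_oracle(tree, table2, False),
        )

    def test_missing_otu_listed(self):
        tree = TreeNode(children=[TreeNode("X", 1.0), TreeNode("Y", 1.0)])
        table = _toy_table()
        table.otu_ids[1] = "MISSING"
        with pytest.raises(ValueError, match="MISSING"):
            unifrac(table, tree)


# ---------------------------------------------------------------------------
# PCoA


class TestPcoa:
    def test_planar_distances_recovered(self, rng):
        pts = rng.random((4, 2)) * 3
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(4)], d))
        rec = np.linalg.norm(
            res.coordinates[:, :2][:, None] - res.coordinates[:, :2][None, :], axis=2
        )
        assert np.allclose(rec, d, atol=1e-9)

    def test_identical_samples_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_negative_eigenvalues_reported(self):
        # star tree metric on 4 taxa is not Euclidean-embeddable as-is
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 1.9
        res = pcoa(DistanceMatrix(list("abcd"), d))
        assert res.eigenvalues.min() < 0  # present in the report
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))


# ---------------------------------------------------------------------------
# jackknifed sample clustering


class TestJackknife:
    def _study_table(self, small_study):
        from mcpdiv.otu_cluster import cluster_greedy, remove_singletons
        from mcpdiv.read_filters import frame_filter

        pooled = []
        for sample, recs in small_study.reads.items():
            pooled.extend(frame_filter(recs, sample=sample).records)
        table = remove_singletons(cluster_greedy(pooled, threshold=0.90))
        tree = build_tree([table.representatives[o] for o in table.otu_ids])
        return table, tree

    def test_no_reps_no_support(self, small_study):
        table, tree = self._study_table(small_study)
        out = sample_upgma_with_jackknife(table, tree, reps=0)
        assert all(n.support is None for n in out.postorder())

    def test_support_range_and_biome_split(self, small_study):
        """Disjoint dominant pools give full support to the biome split."""
        table, tree = self._study_table(small_study)
        out = sample_upgma_with_jackknife(table, tree, reps=30, seed=0)
        supports = [n.support for n in out.postorder() if n.support is not None]
        assert supports and all(0 <= s <= 100 for s in supports)
        lakes = frozenset(s for s, g in small_study.group_of.items() if g == "lake")
        oceans = frozenset(s for s, g in small_study.group_of.items() if g == "ocean")
        for node in out.postorder():
            leafset = frozenset(n.name for n in node.leaves())
            if leafset in (lakes, oceans):
                assert node.support == pytest.approx(100.0)

    def test_depth_error(self, small_study):
        table, tree = self._study_table(small_study)
        with pytest.raises(ValueError):
            sample_upgma_with_jackknife(table, tree, reps=2, depth_fraction=2.5)
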