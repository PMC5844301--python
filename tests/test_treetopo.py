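import itertools

import numpy as np
import pytest

from domsweep import treetopo
from domsweep.treetopo import (
    DistanceMatrix,
    Node,
    bipartitions,
    classify_topology,
    concatenation_experiment,
    neighbor_joining,
    pair_diff_stats,
    pairwise_distance,
    parse_newick,
    region_tree,
)

# ---------------------------------------------------------------------------
# additive-tree oracle helpers


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf names, path-distance matrix, bipartition set)."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [Node(name=nm) for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = rng.uniform(0.05, 1.0)
        b.length = rng.uniform(0.05, 1.0)
        parent = Node(children=[a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    for nd in nodes:
        nd.length = rng.uniform(0.05, 1.0)
    tree = Node(children=nodes)
    # path distances between leaves
    paths = {}

    def walk(nd, acc):
        if nd.is_leaf:
            paths[nd.name] = acc
        for ch in nd.children:
            walk(ch, acc + [(ch, ch.length)])

    walk(tree, [])
    D = np.zeros((n_taxa, n_taxa))
    for x, y in itertools.combinations(range(n_taxa), 2):
        px = paths[names[x]]
        py = paths[names[y]]
        shared = 0
        while shared < min(len(px), len(py)) and px[shared][0] is py[shared][0]:
            shared += 1
        d = sum(l for _, l in px[shared:]) + sum(l for _, l in py[shared:])
        D[x, y] = D[y, x] = d
    return names, D, bipartitions(tree)


# ---------------------------------------------------------------------------


class TestPairwiseDistance:
    def test_identical_point_mass_genotypes(self):
        post = np.zeros((2, 5, 3))
        post[:, :, 1] = 1.0  # both heterozygous everywhere
        cov = np.ones((2, 5), dtype=bool)
        dm = pairwise_distance(post, cov, ["a", "b"], min_overlap=1)
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes(self):
        post = np.zeros((2, 1, 3))
        post[0, 0, 0] = 1.0
        post[1, 0, 2] = 1.0
        cov = np.ones((2, 1), dtype=bool)
        dm = pairwise_distance(post, cov, ["a", "b"], min_overlap=1)
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_expected_difference_soft_posteriors(self):
        post = np.zeros((2, 1, 3))
        post[0, 0] = [0.5, 0.5, 0.0]
        post[1, 0] = [0.0, 0.0, 1.0]
        cov = np.ones((2, 1), dtype=bool)
        dm = pairwise_distance(post, cov, ["a", "b"], min_overlap=1)
        # 0.5 * D(0,2) + 0.5 * D(1,2) = 0.5*1 + 0.5*0.5
        assert dm.d[0, 1] == pytest.approx(0.75)

    def test_coverage_masking(self):
        post = np.zeros((2, 2, 3))
        post[0, :, 0] = 1.0
        post[1, :, 2] = 1.0
        cov = np.array([[True, True], [True, False]])
        dm = pairwise_distance(post, cov, ["a", "b"], min_overlap=1)
        assert dm.n_overlap[0, 1] == 1
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_zero_overlap_raises(self):
        post = np.zeros((2, 1, 3))
        post[:, :, 0] = 1.0
        cov = np.array([[True], [False]])
        with pytest.raises(ValueError, match="co-covered"):
            pairwise_distance(post, cov, ["a", "b"])

    def test_high_depth_matches_true_mismatch(self, small_swept):
        from domsweep.genolik import SiteFilterConfig
        from domsweep.pipeline import snp_stage
        from domsweep.simpop import simulate_reads

        pile = simulate_reads(small_swept, mean_depth=30.0, e=0.001, seed=6)
        # default depth caps target 1-2x data; widen them for 30x reads
        filters = SiteFilterConfig(minInd=8, setMinDepth=8, setMaxDepth=100_000)
        snp = snp_stage(pile, small_swept.individual_ids(), filters=filters)
        dm = pairwise_distance(snp.post, snp.covered, snp.ids, min_overlap=1)
        g = small_swept.genotypes()  # (S, n)
        # restrict the truth to the called SNP coordinates
        site_idx = {p: k for k, p in enumerate(small_swept.positions)}
        rows = [site_idx[p] for p in snp.positions if p in site_idx]
        gt = g[rows]
        a, b = 0, 9
        true_d = np.mean(np.abs(gt[:, a] - gt[:, b]) / 2.0)
        assert dm.d[a, b] == pytest.approx(true_d, rel=0.05)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # classic additive example with ((A,B),(C,D)) structure
        names = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 3.0, 9.0, 10.0],
                [3.0, 0.0, 10.0, 11.0],
                [9.0, 10.0, 0.0, 3.0],
                [10.0, 11.0, 0.0, 0.0],
            ]
        )
        D[3, 2] = D[2, 3] = 3.0
        tree = neighbor_joining(D, names)
        assert frozenset(["A", "B"]) in bipartitions(tree) or frozenset(
            ["C", "D"]
        ) in bipartitions(tree)
        # branch lengths exact on additive input: leaf branch for A is 1
        leaf_lengths = {l.name: l.length for l in tree.leaves()}
        assert leaf_lengths["A"] == pytest.approx(1.0)
        assert leaf_lengths["B"] == pytest.approx(2.0)

    def test_three_taxa_three_point_formula(self):
        D = np.array([[0.0, 4.0, 5.0], [4.0, 0.0, 7.0], [5.0, 7.0, 0.0]])
        tree = neighbor_joining(D, ["a", "b", "c"])
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["a"] == pytest.approx((4 + 5 - 7) / 2)
        assert lengths["b"] == pytest.approx((4 + 7 - 5) / 2)
        assert lengths["c"] == pytest.approx((5 + 7 - 4) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 6, 9, 12])
    def test_random_additive_trees_exact(self, n_taxa, rng):
        for _ in range(10):
            names, D, true_bip = random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(D, names)
            assert bipartitions(tree) == true_bip
            # and the NJ tree reproduces the distances exactly
            D2 = _tree_distances(tree, names)
            assert np.allclose(D, D2, atol=1e-9)

    def test_small_perturbation_keeps_topology(self, rng):
        names, D, true_bip = random_additive_tree(rng, 8)
        noise = rng.uniform(-1e-6, 1e-6, size=D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        tree = neighbor_joining(D + noise, names)
        assert bipartitions(tree) == true_bip

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_nonfinite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(ValueError):
            neighbor_joining(D, ["a", "b", "c"])

    def test_newick_roundtrip(self, rng):
        names, D, bip = random_additive_tree(rng, 6)
        tree = neighbor_joining(D, names)
        back = parse_newick(tree.newick())
        assert sorted(back.leaf_names()) == sorted(names)
        assert bipartitions(back) == bip


def _tree_distances(tree, names):
    idx = {nm: i for i, nm in enumerate(names)}
    D = np.zeros((len(names), len(names)))
    paths = {}

    def walk(nd, acc):
        if nd.is_leaf:
            paths[nd.name] = acc
        for ch in nd.children:
            walk(ch, acc + [(id(ch), ch.length)])

    walk(tree, [])
    for x, y in itertools.combinations(names, 2):
        px, py = paths[x], paths[y]
        shared = 0
        while shared < min(len(px), len(py)) and px[shared][0] == py[shared][0]:
            shared += 1
        d = sum(l for _, l in px[shared:]) + sum(l for _, l in py[shared:])
        D[idx[x], idx[y]] = D[idx[y], idx[x]] = d
    return D


# ---------------------------------------------------------------------------


MONO_TREE = "(((aus_0:1,indica_0:1):1,japonica_0:1):1,(OrIII_0:1,(OrI_0:1,OrII_0:1):1):1):0;"
CONCORDANT_TREE = (
    "(((aus_0:1,OrI_0:1):1,(indica_0:1,OrI_1:1):1):1,"
    "((japonica_0:1,OrIII_0:1):1,OrII_0:1):1):0;"
)


class TestClassifyTopology:
    def test_domesticate_monophyletic(self):
        assert classify_topology(parse_newick(MONO_TREE)) == "domesticate_monophyletic"

    def test_subpop_concordant(self):
        assert classify_topology(parse_newick(CONCORDANT_TREE)) == "subpop_concordant"

    def test_other_when_progenitor_mismatched(self):
        # japonica paired with OrI instead of its OrIII progenitor
        tree = parse_newick(
            "(((aus_0:1,OrIII_0:1):1,(indica_0:1,OrI_1:1):1):1,"
            "((japonica_0:1,OrI_0:1):1,OrII_0:1):1):0;"
        )
        assert classify_topology(tree) == "other"

    def test_missing_outgroup_raises(self):
        tree = parse_newick("((aus_0:1,indica_0:1):1,(japonica_0:1,OrI_0:1):1):0;")
        with pytest.raises(ValueError, match="OrII"):
            classify_topology(tree)

    def test_requires_two_domesticated_subpops(self):
        tree = parse_newick("((aus_0:1,aus_1:1):1,(OrII_0:1,OrII_1:1):1):0;")
        with pytest.raises(ValueError):
            classify_topology(tree)

    def test_invariant_to_leaf_order_and_rotation(self):
        rotated = "((OrIII_0:1,(OrII_0:1,OrI_0:1):1):1,((indica_0:1,aus_0:1):1,japonica_0:1):1):0;"
        assert classify_topology(parse_newick(rotated)) == "domesticate_monophyletic"
        rotated2 = (
            "(OrII_0:1,((OrI_0:1,indica_0:1):1,(aus_0:1,OrI_1:1):1,"
            "(OrIII_0:1,japonica_0:1):1):1):0;"
        )
        # same unrooted shape as CONCORDANT_TREE, written from another node
        assert classify_topology(parse_newick(rotated2)) == "subpop_concordant"

    def test_multi_sample_subpop_clades(self):
        tree = parse_newick(
            "(((aus_0:1,aus_1:1):1,((indica_0:1,indica_1:1):1,(japonica_0:1,japonica_1:1):1):1):1,"
            "((OrI_0:1,OrIII_0:1):1,(OrII_0:1,OrII_1:1):1):1):0;"
        )
        assert classify_topology(tree) == "domesticate_monophyletic"


class TestRegionTree:
    def test_zero_snp_region_errors(self, rng):
        post = rng.dirichlet(np.ones(3), size=(4, 30)).reshape(4, 30, 3)
        cov = np.ones((4, 30), dtype=bool)
        pos = np.arange(30) * 10
        with pytest.raises(ValueError, match="SNPs"):
            region_tree(post, cov, pos, ["aus_0", "indica_0", "japonica_0", "OrII_0"], (1000, 2000))

    def test_whole_sequence_equals_unrestricted(self, small_pile, small_swept):
        from domsweep.pipeline import snp_stage

        snp = snp_stage(small_pile, small_swept.individual_ids())
        t1, c1, n1 = region_tree(
            snp.post, snp.covered, snp.positions, snp.ids, (0, small_swept.L)
        )
        t2, c2, n2 = region_tree(
            snp.post, snp.covered, snp.positions, snp.ids,
            (0, int(snp.positions[-1]) + 1),
        )
        assert n1 == n2 == snp.positions.size
        assert c1 == c2
        assert bipartitions(t1) == bipartitions(t2)


class TestConcatenation:
    def _stats_for(self, tree_kind, rng, n_sites=60):
        """Fabricate pair stats whose distances mimic a mono or concordant
        regime, by building posteriors from idealized genotypes."""
        labels = ["aus_0", "aus_1", "indica_0", "indica_1", "japonica_0",
                  "japonica_1", "OrI_0", "OrI_1", "OrIII_0", "OrII_0"]
        n = len(labels)
        g = np.zeros((n, n_sites), dtype=int)
        if tree_kind == "mono":
            for i in range(6):
                g[i] = 2  # all domesticates share the swept haplotype
            for i in range(6, n):
                g[i] = rng.integers(0, 3, size=n_sites)
        else:
            pair_geno = rng.integers(0, 3, size=(5, n_sites))
            groups = [0, 0, 1, 1, 2, 2, 0, 1, 2, 3]
            for i, grp in enumerate(groups):
                flip = rng.random(n_sites) < 0.02
                g[i] = np.where(flip, rng.integers(0, 3, size=n_sites), pair_geno[grp])
        post = np.zeros((n, n_sites, 3))
        for gt in range(3):
            post[:, :, gt] = g == gt
        cov = np.ones((n, n_sites), dtype=bool)
        return pair_diff_stats(post, cov), labels

    def test_k0_reduces_to_sweep_tree(self, rng):
        (s, c), labels = self._stats_for("mono", rng)
        classes, flip = concatenation_experiment([(s, c)], labels, min_overlap=1)
        assert classes == ["domesticate_monophyletic"]
        assert flip is None

    def test_dilution_flips_classification(self, rng):
        sweep, labels = self._stats_for("mono", rng, n_sites=40)
        neutral = [self._stats_for("concordant", rng, n_sites=400)[0] for _ in range(6)]
        classes, flip = concatenation_experiment(
            [sweep] + neutral, labels, min_overlap=1
        )
        assert classes[0] == "domesticate_monophyletic"
        assert classes[-1] != "domesticate_monophyletic"
        assert flip is not None
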