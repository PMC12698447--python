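import math

import numpy as np
import pytest

from tcrlocus import (bionj, jc_distance, midpoint_root, parse_newick,
                      path_lengths, to_newick, topologies_equal)
from tcrlocus.phylo import DistanceMatrix, TreeNode


# ---------------------------------------------------------------------------
# Jukes-Cantor distances


def test_jc_distance_matches_direct_formula():
    a = "A" * 100
    b = "C" * 10 + "A" * 90  # p = 0.1
    dm = jc_distance({"a": a, "b": b})
    want = -0.75 * math.log(1 - 4 * 0.1 / 3)
    assert dm.matrix[0, 1] == pytest.approx(want, rel=1e-12)
    assert dm.matrix[1, 0] == dm.matrix[0, 1]
    assert dm.matrix[0, 0] == 0.0


def test_jc_pairwise_deletion_ignores_gapped_sites():
    a = "AAAA-AAAAA"
    b = "CAAAAA-AAA"  # shared ungapped sites: 8, mismatches: 1
    dm = jc_distance({"a": a, "b": b})
    want = -0.75 * math.log(1 - 4 * (1 / 8) / 3)
    assert dm.matrix[0, 1] == pytest.approx(want, rel=1e-12)


def test_jc_saturation_and_length_errors():
    with pytest.raises(ValueError, match="saturated"):
        jc_distance({"a": "AAAA", "b": "CCCC"})
    with pytest.raises(ValueError, match="equal aligned length"):
        jc_distance({"a": "AAAA", "b": "AAA"})
    with pytest.raises(ValueError, match="shared ungapped"):
        jc_distance({"a": "--AA", "b": "CC--"})
    with pytest.raises(ValueError, match="at least two"):
        jc_distance({"a": "AAAA"})


# ---------------------------------------------------------------------------
# BIONJ


def _random_additive(rng, n_taxa):
    """Random binary tree with uniform branch lengths; returns (tree, labels,
    exact additive distance matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(label=l) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = TreeNode(children=[(a, float(rng.uniform(0.05, 1.0))),
                                    (b, float(rng.uniform(0.05, 1.0)))])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = TreeNode(children=[(nd, float(rng.uniform(0.05, 1.0)))
                              for nd in nodes])
    pl = path_lengths(tree)
    m = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            m[x, y] = m[y, x] = pl[tuple(sorted((labels[x], labels[y])))]
    return tree, labels, m


def test_bionj_three_taxa_closed_form():
    dm = DistanceMatrix(labels=["a", "b", "c"],
                        matrix=np.array([[0.0, 0.3, 0.5],
                                         [0.3, 0.0, 0.4],
                                         [0.5, 0.4, 0.0]]))
    tree = bionj(dm)
    bl = {c.label: l for c, l in tree.children}
    assert bl["a"] == pytest.approx(0.2, abs=1e-12)
    assert bl["b"] == pytest.approx(0.1, abs=1e-12)
    assert bl["c"] == pytest.approx(0.3, abs=1e-12)


def test_bionj_recovers_hand_built_additive_four_taxon_matrix():
    # ((a:1,b:2):1,(c:3,d:4)) with internal edge 1
    labels = ["a", "b", "c", "d"]
    m = np.array([[0, 3, 5, 6],
                  [3, 0, 6, 7],
                  [5, 6, 0, 7],
                  [6, 7, 7, 0]], dtype=float)
    tree = bionj(DistanceMatrix(labels=labels, matrix=m))
    pl = path_lengths(tree)
    for i in range(4):
        for j in range(i + 1, 4):
            assert pl[(labels[i], labels[j])] == pytest.approx(m[i, j],
                                                               abs=1e-9)
    want = parse_newick("((a:1,b:2):1,c:3,d:4);")
    assert topologies_equal(tree, want)


def test_bionj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(20)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        true_tree, labels, m = _random_additive(rng, n)
        est = bionj(DistanceMatrix(labels=labels, matrix=m))
        assert topologies_equal(est, true_tree)
        pl = path_lengths(est)
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((labels[i], labels[j])))
                assert pl[key] == pytest.approx(m[i, j], abs=1e-9)


def test_bionj_agrees_with_reference_implementation():
    import dendropy
    from dendropy.simulate import treesim

    for seed in range(5):
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
        ref = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                       taxon_namespace=taxa,
                                       num_extant_tips=6,
                                       rng=__import__("random").Random(seed))
        pdm = ref.phylogenetic_distance_matrix()
        labels = [t.label for t in taxa]
        m = np.array([[pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                       for b in labels] for a in labels])
        est = bionj(DistanceMatrix(labels=labels, matrix=m))
        pl = path_lengths(est)
        for i in range(6):
            for j in range(i + 1, 6):
                key = tuple(sorted((labels[i], labels[j])))
                assert pl[key] == pytest.approx(m[i, j], abs=1e-9)


def test_bionj_rejects_invalid_matrices():
    with pytest.raises(ValueError):
        bionj(DistanceMatrix(labels=["a", "b"],
                             matrix=np.array([[0.0, 1.0], [1.0, 0.0]])))
    bad = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.5, 3.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        bionj(DistanceMatrix(labels=list("abc"), matrix=bad))


# ---------------------------------------------------------------------------
# midpoint rooting


def test_midpoint_root_is_idempotent_and_length_preserving():
    rng = np.random.default_rng(30)
    for _ in range(10):
        n = int(rng.integers(4, 8))
        tree, labels, m = _random_additive(rng, n)
        rooted = midpoint_root(tree)
        pl_before = path_lengths(tree)
        pl_after = path_lengths(rooted)
        for key, d in pl_before.items():
            assert pl_after[key] == pytest.approx(d, abs=1e-9)
        again = midpoint_root(rooted)
        assert path_lengths(again) == pytest.approx(pl_after)
        assert topologies_equal(again, rooted)


def test_midpoint_root_balances_the_diameter():
    tree = parse_newick("((a:1,b:5):1,c:2,d:9);")
    rooted = midpoint_root(tree)
    # diameter is b..d = 5+1+9 = 15; each root-side depth is 7.5
    depths = {}

    def walk(node, acc):
        if node.is_leaf():
            depths[node.label] = acc
        for c, l in node.children:
            walk(c, acc + l)

    walk(rooted, 0.0)
    assert max(depths.values()) == pytest.approx(7.5, abs=1e-12)
    assert depths["b"] == pytest.approx(7.5)
    assert depths["d"] == pytest.approx(7.5)


def test_midpoint_root_errors():
    with pytest.raises(ValueError):
        midpoint_root(TreeNode(label="only"))
    flat = parse_newick("(a:0,b:0,c:0);")
    with pytest.raises(ValueError, match="zero total branch length"):
        midpoint_root(flat)


# ---------------------------------------------------------------------------
# Newick I/O


def test_newick_round_trip_preserves_structure():
    rng = np.random.default_rng(40)
    for _ in range(10):
        tree, _, _ = _random_additive(rng, int(rng.integers(4, 8)))
        back = parse_newick(to_newick(tree))
        assert topologies_equal(back, tree)
        assert path_lengths(back) == pytest.approx(path_lengths(tree),
                                                   rel=1e-9)


def test_newick_parse_errors():
    with pytest.raises(ValueError, match="end with"):
        parse_newick("(a:1,b:2)")
    with pytest.raises(ValueError, match="trailing"):
        parse_newick("(a:1,b:2);junk;")


def test_topologies_equal_distinguishes_quartets():
    t1 = parse_newick("((a:1,b:1):1,c:1,d:1);")
    t2 = parse_newick("((a:1,c:1):1,b:1,d:1);")
    assert topologies_equal(t1, t1)
    assert not topologies_equal(t1, t2)
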