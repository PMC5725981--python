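"""Neighbor joining, bootstrap supports and clade purity."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from setfam.phylogeny import (bootstrap_support, class_purity, nj_tree,
                              pdistance_matrix, read_phylip, write_newick,
                              write_phylip)
from setfam.simulate import generate_family_sequences

# --------------------------------------------------------------------------
# random additive trees (the generating tree is the oracle)

def random_tree(n, rng):
    """Random unrooted binary tree with positive lengths, as an edge list."""
    nodes = [f"T{i}" for i in range(3)]
    edges = {}                 # (a, b) -> length
    center = "I0"
    internal = 1
    for t in nodes:
        edges[(t, center)] = float(rng.uniform(0.5, 3.0))
    for i in range(3, n):
        leaf = f"T{i}"
        a, b = list(edges)[int(rng.integers(0, len(edges)))]
        length = edges.pop((a, b))
        mid = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8)) * length
        edges[(a, mid)] = split
        edges[(mid, b)] = length - split
        edges[(leaf, mid)] = float(rng.uniform(0.5, 3.0))
    return edges


def tree_distances(edges, n):
    import networkx as nx
    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b, weight=w)
    ids = [f"T{i}" for i in range(n)]
    m = np.zeros((n, n))
    for i, a in enumerate(ids):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(ids):
            m[i, j] = lengths[b]
    m = (m + m.T) / 2          # remove float asymmetry from path sums
    np.fill_diagonal(m, 0)
    return DistanceMatrix(m, ids)


def tree_bipartitions_from_edges(edges, n):
    import networkx as nx
    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b)
    ids = set(f"T{i}" for i in range(n))
    anchor = min(ids)
    bps = set()
    for a, b in list(g.edges):
        g.remove_edge(a, b)
        side = set(nx.node_connected_component(g, a)) & ids
        g.add_edge(a, b)
        if 1 < len(side) < n - 1:
            bps.add(frozenset(side if anchor not in side else ids - side))
    return bps


def nj_bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    bps = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            bps.add(side if anchor not in side else leaves - side)
    return bps


def four_point_split(dm):
    """The valid 4-taxon split by the four-point condition (oracle)."""
    a, b, c, d = dm.ids
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, d])]):
            dm[a, b] + dm[c, d],
        frozenset([frozenset([a, c]), frozenset([b, d])]):
            dm[a, c] + dm[b, d],
        frozenset([frozenset([a, d]), frozenset([b, c])]):
            dm[a, d] + dm[b, c],
    }
    return min(sums, key=sums.get)


def test_nj_recovers_4_taxon_tree_exactly():
    # ((A:1,B:2):1,(C:3,D:1)) -> additive distances
    ids = ["A", "B", "C", "D"]
    d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
         ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4}
    m = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = v
    tree = nj_tree(DistanceMatrix(m, ids))
    assert nj_bipartitions(tree) == {frozenset({"C", "D"})}
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}
    inner = [n for n in tree.non_tips(include_self=False)][0]
    assert inner.length == pytest.approx(1.0)


def test_three_taxa_closed_form():
    m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = nj_tree(DistanceMatrix(m, ["A", "B", "C"]))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_exact_on_random_additive_matrices(n):
    rng = np.random.default_rng(100 + n)
    for rep in range(5):
        edges = random_tree(n, rng)
        dm = tree_distances(edges, n)
        tree = nj_tree(dm)
        assert nj_bipartitions(tree) == tree_bipartitions_from_edges(edges, n)
        if n == 4:
            split = four_point_split(dm)
            got = nj_bipartitions(tree).pop()
            assert frozenset([got, frozenset(dm.ids) - got]) == split


def test_nj_agrees_with_skbio_on_noisy_matrices():
    rng = np.random.default_rng(17)
    for n in (5, 8):
        edges = random_tree(n, rng)
        dm = tree_distances(edges, n)
        noisy = dm.data + rng.uniform(0, 0.02, dm.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ndm = DistanceMatrix(noisy, dm.ids)
        ours = nj_tree(ndm)
        theirs = skbio_nj(ndm)
        assert nj_bipartitions(ours) == nj_bipartitions(theirs)


def test_nonsymmetric_matrix_rejected():
    with pytest.raises(Exception):
        DistanceMatrix(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float),
                       ["a", "b", "c"])


def test_too_few_taxa_rejected():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))


# --------------------------------------------------------------------------
# p-distances

def test_identical_sequences_distance_zero():
    s = "MKVLASETWQRYHDNNPACDEFGHIKLMNPQRST"
    dm = pdistance_matrix({"a": s, "b": s, "c": s})
    assert (dm.data == 0).all()


def test_known_substitution_fraction():
    s = "A" * 100
    t = "A" * 95 + "W" * 5
    dm = pdistance_matrix({"a": s, "b": t, "c": s})
    assert dm["a", "b"] == pytest.approx(5 / 100)


def test_pdistance_symmetric_zero_diagonal():
    seqs, _ = generate_family_sequences(seed=21, n_per_family=1)
    dm = pdistance_matrix(seqs)
    assert np.allclose(dm.data, dm.data.T)
    assert np.allclose(np.diag(dm.data), 0)
    assert (dm.data >= 0).all() and (dm.data <= 1).all()


def test_phylip_roundtrip():
    seqs, _ = generate_family_sequences(seed=22, n_per_family=1)
    dm = pdistance_matrix(seqs)
    back = read_phylip(write_phylip(dm))
    assert list(back.ids) == list(dm.ids)
    assert np.allclose(back.data, dm.data, atol=1e-6)


# --------------------------------------------------------------------------
# bootstrap

def _two_cluster_seqs(seed=30, n=5):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aas, size=120))
    b = "".join(rng.choice(aas, size=120))
    seqs = {}
    from setfam.simulate import mutate
    for i in range(n):
        seqs[f"a{i}"] = mutate(a, 0.03, rng)
        seqs[f"b{i}"] = mutate(b, 0.03, rng)
    return seqs


def test_separating_edge_gets_high_support():
    seqs = _two_cluster_seqs()
    tree = bootstrap_support(seqs, n_reps=100, seed=1)
    split = frozenset(k for k in seqs if k.startswith("b"))
    bps = {}
    leaves = frozenset(seqs)
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if anchor not in side else leaves - side
        bps[canon] = node.support
    assert bps[split] >= 95


def test_single_replicate_supports_binary():
    seqs = _two_cluster_seqs(n=3)
    tree = bootstrap_support(seqs, n_reps=1, seed=2)
    sups = [n.support for n in tree.non_tips(include_self=False)
            if hasattr(n, "support")]
    assert sups and all(s in (0.0, 100.0) for s in sups)


def test_bootstrap_deterministic_given_seed():
    seqs = _two_cluster_seqs(n=3)
    t1 = bootstrap_support(seqs, n_reps=25, seed=7)
    t2 = bootstrap_support(seqs, n_reps=25, seed=7)
    assert write_newick(t1) == write_newick(t2)


def test_bootstrap_invariant_under_leaf_order():
    seqs = _two_cluster_seqs(n=3)
    rev = dict(reversed(list(seqs.items())))
    sup = lambda t: sorted(n.support
                           for n in t.non_tips(include_self=False))
    assert sup(bootstrap_support(seqs, n_reps=25, seed=7)) == \
        sup(bootstrap_support(rev, n_reps=25, seed=7))


# --------------------------------------------------------------------------
# purity

def test_perfect_family_clades_score_one():
    seqs, labels = generate_family_sequences(seed=31, n_per_family=5)
    tree = nj_tree(pdistance_matrix(seqs))
    purity = class_purity(tree, labels)
    assert purity["mean"] == pytest.approx(1.0)


def test_single_family_trivially_pure():
    seqs, labels = generate_family_sequences(seed=32, families=("Ash",),
                                             n_per_family=4)
    tree = nj_tree(pdistance_matrix(seqs))
    assert class_purity(tree, labels)["Ash"] == 1.0


def test_purity_matches_exhaustive_edge_scan():
    """Interleaved labels on a small tree, scored by brute force."""
    ids = [f"T{i}" for i in range(6)]
    rng = np.random.default_rng(33)
    edges = random_tree(6, rng)
    dm = tree_distances(edges, 6)
    tree = nj_tree(dm)
    labels = {t: ("X" if i % 2 == 0 else "Y") for i, t in enumerate(ids)}
    got = class_purity(tree, labels)
    # brute force over all edges of the NJ tree (plus the whole-tree side)
    sides = {frozenset([l]) for l in ids} | {frozenset(ids)}
    for node in tree.non_tips(include_self=False):
        sides.add(frozenset(t.name for t in node.tips()))
    sides |= {frozenset(ids) - s for s in sides}
    for fam in ("X", "Y"):
        fset = frozenset(t for t in ids if labels[t] == fam)
        want = max(len(s & fset) / len(s | fset) for s in sides if s)
        assert got[fam] == pytest.approx(want)


def test_unlabeled_leaf_rejected():
    seqs, labels = generate_family_sequences(seed=34, n_per_family=2)
    tree = nj_tree(pdistance_matrix(seqs))
    labels = dict(list(labels.items())[:-1])
    with pytest.raises(ValueError):
        class_purity(tree, labels)
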