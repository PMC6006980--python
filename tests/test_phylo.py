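import random

import numpy as np
import pytest

from pksline import (
    DistanceMatrix,
    PhyloTree,
    bootstrap,
    nj_tree,
    pairwise_align,
    progressive_msa,
)
AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- pairwise

def test_identical_sequences_align_without_gaps():
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    seq = "MKWVTFISLLLFSSAYS"
    a, b, score = pairwise_align(seq, seq)
    assert a == b == seq
    assert score == sum(blosum[c, c] for c in seq)


def test_textbook_pair_matches_independent_dp():
    """Score agrees with an independently implemented aligner."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    oracle = Align.PairwiseAligner()
    oracle.substitution_matrix = substitution_matrices.load("BLOSUM62")
    oracle.open_gap_score = -11
    oracle.extend_gap_score = -1
    oracle.mode = "global"

    _, _, score = pairwise_align("HEAGAWGHEE", "PAWHEAE")
    assert score == pytest.approx(oracle.score("HEAGAWGHEE", "PAWHEAE"))

    rng = random.Random(11)
    for _ in range(25):
        a = "".join(rng.choice(AA20) for _ in range(rng.randint(4, 70)))
        b = "".join(rng.choice(AA20) for _ in range(rng.randint(4, 70)))
        aa, bb, s = pairwise_align(a, b)
        assert aa.replace("-", "") == a and bb.replace("-", "") == b
        assert len(aa) == len(bb)
        assert s == pytest.approx(oracle.score(a, b))


def test_pairwise_score_symmetry():
    rng = random.Random(3)
    for _ in range(10):
        a = "".join(rng.choice(AA20) for _ in range(rng.randint(5, 40)))
        b = "".join(rng.choice(AA20) for _ in range(rng.randint(5, 40)))
        assert pairwise_align(a, b)[2] == pytest.approx(pairwise_align(b, a)[2])


def test_pairwise_rejects_empty():
    with pytest.raises(ValueError):
        pairwise_align("", "MK")


# ---------------------------------------------------------------- MSA

def test_msa_of_two_equals_pairwise():
    a, b = "MKWVTFISLL", "MKWTFISLL"
    pa, pb, _ = pairwise_align(a, b)
    msa = progressive_msa([("a", a), ("b", b)])
    assert msa == [("a", pa), ("b", pb)]


def test_msa_identical_records_gap_free():
    seq = "MKWVTFISLLLF"
    msa = progressive_msa([("a", seq), ("b", seq), ("c", seq)])
    assert all(row == seq for _, row in msa)


def test_msa_single_record_unchanged():
    assert progressive_msa([("a", "MKL")]) == [("a", "MKL")]


def test_msa_recovers_family_columns():
    """8 noisy descendants of one ancestor: >=90% of columns stay ungapped."""
    rng = random.Random(17)
    ancestor = "".join(rng.choice(AA20) for _ in range(120))
    records = []
    for k in range(8):
        seq = [c if rng.random() > 0.05 else rng.choice(AA20) for c in ancestor]
        records.append((f"leaf{k}", "".join(seq)))
    msa = progressive_msa(records)
    L = len(msa[0][1])
    assert L >= 120  # at least the longest input
    ungapped = sum(
        1 for col in range(L) if all(row[col] != "-" for _, row in msa)
    )
    assert ungapped >= 0.90 * 120


# ---------------------------------------------------------------- NJ

def _tree_distances(n, seed):
    """Random binary tree over n leaves; returns its additive matrix and
    the set of non-trivial bipartitions (the topology oracle)."""
    rng = random.Random(seed)
    nodes = {i: frozenset([f"t{i}"]) for i in range(n)}
    parent, blen = {}, {}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i = active.pop(rng.randrange(len(active)))
        j = active.pop(rng.randrange(len(active)))
        parent[i], parent[j] = nxt, nxt
        blen[i] = rng.uniform(0.2, 1.0)
        blen[j] = rng.uniform(0.2, 1.0)
        nodes[nxt] = nodes[i] | nodes[j]
        active.append(nxt)
        nxt += 1

    labels = tuple(f"t{i}" for i in range(n))
    allset = frozenset(labels)
    anchor = min(labels)

    def chain(x):
        out = []
        while x in parent:
            out.append(x)
            x = parent[x]
        return out

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = chain(i), chain(j)
            common = next(a for a in [i] + [parent[x] for x in ci]
                          if a in set([j] + [parent[x] for x in cj]))
            d = 0.0
            x = i
            while x != common:
                d += blen[x]
                x = parent[x]
            x = j
            while x != common:
                d += blen[x]
                x = parent[x]
            D[i, j] = D[j, i] = d

    bips = set()
    for x, side in nodes.items():
        if 2 <= len(side) <= n - 2:
            key = side if anchor not in side else allset - side
            if 2 <= len(key) <= n - 2:
                bips.add(key)
    return labels, D, bips


def test_nj_recovers_additive_four_taxon_matrix():
    labels, D, bips = _tree_distances(4, seed=0)
    tree = nj_tree(DistanceMatrix(labels, D))
    assert set(tree.bipartitions()) == bips


def test_nj_recovers_random_additive_trees_up_to_8_leaves():
    """NJ is consistent on additive matrices (property over random trees)."""
    for n in range(4, 9):
        for seed in range(6):
            labels, D, bips = _tree_distances(n, seed=seed)
            tree = nj_tree(DistanceMatrix(labels, D))
            assert set(tree.bipartitions()) == bips, (n, seed)


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(("a", "b", "c"), D))
    lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
    assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}


def test_nj_matches_upgma_on_ultrametric_matrix():
    from scipy.cluster.hierarchy import linkage, to_tree
    labels, D, _ = _tree_distances(6, seed=2)
    # make it ultrametric: distances from a clock-like tree
    rng = random.Random(9)
    n = 6
    # build clock tree: successive pairings at increasing heights
    heights = sorted(rng.uniform(1, 10) for _ in range(n - 1))
    clusters = [[i] for i in range(n)]
    U = np.zeros((n, n))
    for h in heights:
        a = clusters.pop(rng.randrange(len(clusters)))
        b = clusters.pop(rng.randrange(len(clusters)))
        for i in a:
            for j in b:
                U[i, j] = U[j, i] = 2 * h
        clusters.append(a + b)
    labels = tuple(f"t{i}" for i in range(n))
    tree = nj_tree(DistanceMatrix(labels, U))

    Z = linkage(U[np.triu_indices(n, 1)], method="average")
    allset = frozenset(labels)
    anchor = min(labels)

    def upgma_bips():
        out = set()
        node = to_tree(Z)

        def walk(nd):
            if nd.is_leaf():
                return frozenset([labels[nd.id]])
            side = walk(nd.left) | walk(nd.right)
            if 2 <= len(side) <= n - 2 or 2 <= len(allset - side) <= n - 2:
                key = side if anchor not in side else allset - side
                if 2 <= len(key) <= n - 2:
                    out.add(key)
            return side

        walk(node)
        return out

    assert set(tree.bipartitions()) == upgma_bips()


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError, match="3 taxa"):
        nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("a", "b", "c"),
                       np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))
    with pytest.raises(ValueError, match="negative"):
        DistanceMatrix(("a", "b", "c"),
                       np.array([[0, -1, 2], [-1, 0, 3], [2, 3, 0.0]]))


def test_negative_branch_lengths_clamped():
    # a matrix known to force a negative NJ branch length
    D = np.array([
        [0.0, 0.1, 0.4, 0.45],
        [0.1, 0.0, 0.45, 0.4],
        [0.4, 0.45, 0.0, 0.1],
        [0.45, 0.4, 0.1, 0.0],
    ])
    tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), D))

    def walk(node):
        assert node.length >= 0.0
        assert node.raw_length <= node.length + 1e-12 or \
            node.raw_length == pytest.approx(node.length)
        for c in node.children:
            walk(c)

    walk(tree.root)


# ---------------------------------------------------------------- bootstrap

def _two_clade_alignment():
    rng = random.Random(4)
    a = "".join(rng.choice(AA20) for _ in range(80))
    b = "".join(rng.choice(AA20) for _ in range(80))
    rows = []
    for k in range(3):
        rows.append((f"a{k}", a))
        rows.append((f"b{k}", b))
    return rows


def test_bootstrap_separated_clades_full_support():
    tree = bootstrap(_two_clade_alignment(), n_replicates=50, seed=1)
    supports = [s for _, (_, s) in tree.bipartitions().items()]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_single_replicate_is_binary():
    rng = random.Random(8)
    rows = [(f"x{k}", "".join(rng.choice(AA20) for _ in range(40)))
            for k in range(6)]
    tree = bootstrap(rows, n_replicates=1, seed=2)
    supports = {s for _, (_, s) in tree.bipartitions().items() if s is not None}
    assert supports <= {0.0, 100.0}


def test_bootstrap_deterministic_under_seed():
    rows = _two_clade_alignment()
    t1 = bootstrap(rows, n_replicates=30, seed=9)
    t2 = bootstrap(rows, n_replicates=30, seed=9)
    s1 = {k: s for k, (_, s) in t1.bipartitions().items()}
    s2 = {k: s for k, (_, s) in t2.bipartitions().items()}
    assert s1 == s2
    assert t1.to_newick() == t2.to_newick()


def test_bootstrap_supports_are_exact_replicate_fractions():
    rng = random.Random(21)
    rows = [(f"x{k}", "".join(rng.choice("ACDE") for _ in range(30)))
            for k in range(5)]
    n = 40
    tree = bootstrap(rows, n_replicates=n, seed=5)
    for _, (_, s) in tree.bipartitions().items():
        if s is not None:
            count = s * n / 100.0
            assert count == pytest.approx(round(count))
            assert 0.0 <= s <= 100.0


# ---------------------------------------------------------------- newick

def test_newick_roundtrip_topology_lengths_supports():
    labels, D, _ = _tree_distances(6, seed=5)
    tree = nj_tree(DistanceMatrix(labels, D))
    for key, (node, _) in tree.bipartitions().items():
        node.support = 87.0
    text = tree.to_newick()
    back = PhyloTree.from_newick(text)
    assert set(back.bipartitions()) == set(tree.bipartitions())
    orig = {n.name: n.length for n in tree.root.leaves()}
    round_ = {n.name: n.length for n in back.root.leaves()}
    for name in orig:
        assert round_[name] == pytest.approx(orig[name], abs=1e-5)
    supports = [s for _, (_, s) in back.bipartitions().items()]
    assert supports and all(s == 87.0 for s in supports)
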