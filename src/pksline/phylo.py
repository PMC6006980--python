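"""Neighbor-joining trees with bootstrap support.

Distances default to p-distances on aligned sequences with pairwise gap
deletion. Neighbor joining follows the classic Q-matrix formulation with a
deterministic tie-break (lexicographically smallest label pair, internal
nodes inheriting the smallest leaf label of their clade). Negative branch
lengths are clamped to zero for display; the raw value is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import alignment_pdistance, progressive_msa, ScoreParams


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over labelled taxa."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances are not allowed")


class TreeNode:
    """Node of an (un)rooted tree; children carried with branch lengths."""

    __slots__ = ("name", "children", "length", "raw_length", "support")

    def __init__(self, name=None, children=None, length=0.0,
                 raw_length=None, support=None):
        self.name = name
        self.children = children or []
        self.length = length
        self.raw_length = length if raw_length is None else raw_length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())


@dataclass
class PhyloTree:
    """An unrooted tree (root node of degree >= 3 for n >= 3 taxa)."""

    root: TreeNode
    attributes: dict = field(default_factory=dict)

    @property
    def labels(self) -> tuple:
        return tuple(sorted(self.root.leaf_names()))

    def bipartitions(self) -> dict:
        """Non-trivial splits as canonical frozensets -> (node, support).

        Each internal edge is keyed by the leaf set on the side NOT
        containing the alphabetically first taxon.
        """
        all_leaves = self.root.leaf_names()
        anchor = min(all_leaves)
        out = {}

        def walk(node):
            for child in node.children:
                side = child.leaf_names()
                if 1 < len(side) < len(all_leaves) - 0:
                    key = side if anchor not in side else all_leaves - side
                    if 1 < len(key) < len(all_leaves):
                        out[key] = (child, child.support)
                walk(child)

        walk(self.root)
        return out

    def clades_containing(self, label: str) -> list:
        """Leaf-set sides of edges that contain ``label``, smallest first."""
        all_leaves = self.root.leaf_names()
        sides = []

        def walk(node):
            for child in node.children:
                side = child.leaf_names()
                if len(side) < len(all_leaves):
                    containing = side if label in side else all_leaves - side
                    if 1 < len(containing) < len(all_leaves):
                        sides.append((containing, child.support))
                walk(child)

        walk(self.root)
        uniq = {}
        for side, support in sides:
            if side not in uniq or uniq[side] is None:
                uniq[side] = support
        return sorted(uniq.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))

    def to_newick(self, precision: int = 6) -> str:
        def fmt(node):
            if node.is_leaf():
                return f"{node.name}:{node.length:.{precision}f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.{precision}f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        s = text.strip().rstrip(";")
        pos = 0

        def parse():
            nonlocal pos
            node = TreeNode()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse())
                    if s[pos] == ",":
                        pos += 1
                    else:
                        break
                assert s[pos] == ")", f"unbalanced newick at {pos}"
                pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos]
            if label:
                if node.children:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
                else:
                    node.name = label
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",():;":
                    pos += 1
                node.length = float(s[start:pos])
                node.raw_length = node.length
            return node

        return cls(root=parse())


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou-Nei, Studier-Keppler Q criterion).

    Ties in Q are broken by the lexicographically smallest label pair,
    where an internal node carries the smallest leaf label beneath it.
    Negative branch lengths are clamped to zero (raw value retained).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    tags = [str(label) for label in dm.labels]  # tie-break keys
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def attach(node, length):
        node.raw_length = float(length)
        node.length = float(max(0.0, length))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        pairs = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = None
        for i, j in pairs:
            if i >= j:
                continue
            key = tuple(sorted((tags[active[i]], tags[active[j]])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        attach(nodes[ai], li)
        attach(nodes[aj], lj)
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        # distances from the new node to the others
        new_row = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        tags.append(min(tags[ai], tags[aj]))
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # resolve the final three by the three-point formulas
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        attach(node, length)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def tree_from_alignment(rows: Sequence[tuple], dist_fn=alignment_pdistance) -> PhyloTree:
    """p-distance + NJ over an alignment given as (label, aligned_seq)."""
    labels = [lab for lab, _ in rows]
    d = dist_fn([seq for _, seq in rows])
    return nj_tree(DistanceMatrix(labels=tuple(labels), values=d))


def bootstrap(alignment: Sequence[tuple], n_replicates: int, seed: int) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; support of each
    original-tree bipartition is the percentage of replicate trees that
    contain it. Reproducible under a fixed seed.
    """
    alignment = list(alignment)
    L = len(alignment[0][1])
    if L < 2:
        raise ValueError("bootstrap requires an alignment with >= 2 columns")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = [lab for lab, _ in alignment]
    tree = tree_from_alignment(alignment)
    target = tree.bipartitions()
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    rows = np.array([list(seq) for _, seq in alignment])
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_rows = ["".join(r) for r in rows[:, cols]]
        rep_tree = tree_from_alignment(list(zip(labels, rep_rows)))
        rep_bip = rep_tree.bipartitions()
        for key in counts:
            if key in rep_bip:
                counts[key] += 1

    def annotate(node):
        for child in node.children:
            side = child.leaf_names()
            if len(side) > 1:
                all_leaves = tree.root.leaf_names()
                anchor = min(all_leaves)
                key = side if anchor not in side else all_leaves - side
                if key in counts:
                    child.support = 100.0 * counts[key] / n_replicates
            annotate(child)

    annotate(tree.root)
    tree.attributes["n_bootstrap"] = n_replicates
    tree.attributes["seed"] = seed
    tree.attributes["scale"] = "substitutions per position (p-distance)"
    return tree


def at_alignment_and_tree(records, n_bootstrap: int, seed: int,
                          score_params: Optional[ScoreParams] = None):
    """Convenience: progressive MSA then bootstrap NJ over protein records."""
    msa = progressive_msa(records, score_params)
    if n_bootstrap >= 1:
        return msa, bootstrap(msa, n_bootstrap, seed)
    return msa, tree_from_alignment(msa)
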