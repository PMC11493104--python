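"""Neighbor-joining trees with bootstrap support and outgroup rooting.

Implements the classic NJ agglomeration on the Q-criterion: at each step the
pair ``(i, j)`` minimizing ``Q(i, j) = (m - 2) d_ij - r_i - r_j`` is joined,
with ties broken deterministically by the lowest (row, column) index pair.
NJ is exact on additive distance matrices — it recovers both the unique
topology and all branch lengths.  Negative branch-length estimates (possible
on non-additive input) are clamped to zero with the original value retained
as an annotation.

Trees are held unrooted as a trifurcation at an internal "root" node and can
be rooted on an outgroup's pendant edge.  Bootstrap support resamples
alignment columns with replacement, rebuilds the NJ tree and counts how
often each internal bipartition of the reference tree reappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .distances import DistanceMatrix, hamming_matrix
from .errors import MetadataError, UndefinedStatisticError
from .seqio import Alignment


@dataclass
class Node:
    """Tree node; ``length``/``support`` describe the edge to the parent."""

    label: str | None = None
    length: float = 0.0
    raw_length: float | None = None  # pre-clamp estimate when negative
    support: float | None = None  # bootstrap percentage, internal edges only
    zero_length_flag: bool = False  # support undefined on zero-length edges
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """Binary tree over haplotype labels; unrooted trees hold a trifurcation
    at ``root``."""

    root: Node
    rooted: bool = False

    def leaves(self) -> list[str]:
        return [n.label for n in self.root.walk() if n.is_leaf]

    def _leafset(self, node: Node) -> frozenset[str]:
        return frozenset(n.label for n in node.walk() if n.is_leaf)

    def edge_bipartitions(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` -> canonical non-trivial bipartition of the edge
        above ``node``.

        A bipartition is canonicalized as the side *not* containing the
        lexicographically smallest leaf, so it is comparable across trees
        with the same leaf set regardless of rooting.
        """
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: dict[int, frozenset[str]] = {}
        for node in self.root.walk():
            if node is self.root:
                continue
            side = self._leafset(node)
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[id(node)] = side
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Set of non-trivial bipartitions (see :meth:`edge_bipartitions`)."""
        return set(self.edge_bipartitions().values())

    def to_newick(self) -> str:
        return to_newick(self)


def _clamp(node: Node, value: float) -> None:
    if value < 0:
        node.raw_length = value
        node.length = 0.0
    else:
        node.length = value


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining; returns an unrooted tree (trifurcating root).

    Requires at least three taxa.  Deterministic: ties in the Q-criterion are
    resolved by the lowest (row, column) pair of current matrix indices.
    """
    n = len(dist)
    if n < 3:
        raise UndefinedStatisticError("neighbor joining requires >= 3 taxa")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dist.D
    nodes: list[Node] = [Node(label=sid) for sid in dist.ids]
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        r = {i: float(sum(D[i, j] for j in active if j != i)) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q:  # strict: first minimum wins -> lowest pair
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        _clamp(nodes[i], li)
        _clamp(nodes[j], lj)
        parent = Node(children=[nodes[i], nodes[j]])
        for k in active:
            if k not in (i, j):
                D[nxt, k] = D[k, nxt] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = D[a, b] - la
    lc = D[a, c] - la
    _clamp(nodes[a], la)
    _clamp(nodes[b], lb)
    _clamp(nodes[c], lc)
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, rooted=False)


def _pairwise_hamming(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        D[i, i + 1 :] = np.count_nonzero(enc[i + 1 :] != enc[i], axis=1)
    return D + D.T


def bootstrap_support(
    aln: Alignment,
    B: int = 1000,
    *,
    seed: int,
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap for the NJ tree of ``aln``.

    Builds the reference NJ tree from normalized Hamming (p-) distances, then
    resamples the ``L`` alignment columns with replacement ``B`` times,
    rebuilds the tree and scores each internal bipartition of the reference
    tree by its recovery percentage.  Supports are written onto the reference
    tree's internal nodes; zero-length internal edges are additionally
    flagged, since support on a zero-length edge is not meaningful.

    Returns ``(reference_tree, {bipartition: percent})``.
    """
    if B < 1:
        raise UndefinedStatisticError("bootstrap requires B >= 1")
    ref_tree = neighbor_joining(hamming_matrix(aln, normalize=True))
    edge_bips = ref_tree.edge_bipartitions()
    counts: dict[frozenset[str], int] = {bip: 0 for bip in edge_bips.values()}

    enc = np.frombuffer(
        "".join(aln.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), -1)
    L = aln.L
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        D = _pairwise_hamming(enc[:, cols]) / L
        rep = neighbor_joining(DistanceMatrix(list(aln.ids), D))
        for bip in rep.bipartitions():
            if bip in counts:
                counts[bip] += 1

    supports = {bip: 100.0 * c / B for bip, c in counts.items()}
    for node in ref_tree.root.walk():
        if node is ref_tree.root or node.is_leaf:
            continue
        bip = edge_bips.get(id(node))
        if bip is not None:
            node.support = supports[bip]
        if node.length <= 1e-12:  # zero up to floating-point noise
            node.zero_length_flag = True
    return ref_tree, supports


def _adjacency(tree: PhyloTree) -> dict[int, list[tuple[Node, float, float | None]]]:
    adj: dict[int, list[tuple[Node, float, float | None]]] = {}
    for node in tree.root.walk():
        for child in node.children:
            adj.setdefault(id(node), []).append((child, child.length, child.support))
            adj.setdefault(id(child), []).append((node, child.length, child.support))
    return adj


def root_with_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root the tree on the outgroup's pendant edge (bisected at its middle).

    The ingroup topology and all bipartitions are preserved; edge supports
    travel with their edges.  Raises :class:`MetadataError` if the outgroup
    is not a leaf of the tree.
    """
    leaves = {n.label: n for n in tree.root.walk() if n.is_leaf}
    if outgroup_label not in leaves:
        raise MetadataError(f"outgroup {outgroup_label!r} is not a leaf")
    adj = _adjacency(tree)
    og = leaves[outgroup_label]
    (neighbor, length, support), = adj[id(og)]

    def orient(node: Node, parent: Node, length: float, support: float | None) -> Node:
        fresh = Node(
            label=node.label,
            length=length,
            raw_length=node.raw_length,
            zero_length_flag=node.zero_length_flag,
        )
        for nbr, l, s in adj[id(node)]:
            if nbr is not parent:
                fresh.children.append(orient(nbr, node, l, s))
        # the support belongs to the edge; keep it only on internal edges
        fresh.support = support if fresh.children else None
        return fresh

    new_og = Node(label=og.label, length=length / 2.0)
    ingroup = orient(neighbor, og, length / 2.0, support)
    root = Node(children=[new_og, ingroup])
    return PhyloTree(root, rooted=True)


def _fmt(x: float) -> str:
    if abs(x) < 1e-12:  # swallow floating-point noise on zero-length edges
        x = 0.0
    return format(x, "g")


def to_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths; bootstrap supports appear as internal
    node labels (standard newick convention)."""

    def render(node: Node) -> str:
        if node.is_leaf:
            return f"{node.label}:{_fmt(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        sup = "" if node.support is None else _fmt(node.support)
        return f"({inner}){sup}:{_fmt(node.length)}"

    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"
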