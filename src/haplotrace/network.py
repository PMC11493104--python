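"""Minimum-spanning haplotype networks and mutational-branch clustering.

The minimum spanning network (MSN) is the union of all minimum spanning
trees of the complete haplotype graph weighted by substitution count: an
edge ``(u, v)`` of weight ``w`` belongs to the network iff ``u`` and ``v``
cannot be connected using only edges of weight ``< w``.  This formulation
needs no tie-breaking, so the result is independent of input order.  A
relaxation parameter ``epsilon`` lowers the exclusion threshold to
``< w - epsilon``, admitting slightly longer alternative connections.

Clusters — groups of haplotypes separated by long mutational branches — are
the connected components left after removing all edges of weight >= a cut
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .distances import DistanceMatrix, hamming_matrix
from .errors import BoundsError
from .haplotypes import HaplotypeCatalog
from .seqio import Alignment


@dataclass
class HaploNetwork:
    """Haplotype nodes plus minimum-spanning-network edges.

    ``graph`` nodes carry ``size`` (number of carriers) and optional
    ``group_counts`` attributes; edges carry integer ``weight`` =
    substitution count.  ``cluster_id`` is filled by
    :func:`network_clusters`.
    """

    graph: nx.Graph
    cluster_id: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        """Edge list ``(u, v, weight)`` sorted for stable output."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, data["weight"]))
        return sorted(out)


def minimum_spanning_network(
    dist: DistanceMatrix,
    epsilon: float = 0,
    node_attrs: dict[str, dict] | None = None,
) -> HaploNetwork:
    """Build the (epsilon-relaxed) minimum spanning network.

    With the default ``epsilon=0`` the edge set equals the union of all
    minimum spanning trees.  All candidate edges of a given weight are
    evaluated against the same connectivity snapshot, so inclusion is
    simultaneous and order-free.  A single-node matrix yields an empty edge
    set.
    """
    if epsilon < 0:
        raise BoundsError("epsilon must be >= 0")
    labels = dist.ids
    G = nx.Graph()
    G.add_nodes_from(labels)
    if node_attrs:
        for node, attrs in node_attrs.items():
            G.nodes[node].update(attrs)

    by_weight: dict[float, list[tuple[str, str]]] = {}
    for i, u in enumerate(labels):
        for j in range(i + 1, len(labels)):
            w = float(dist.D[i, j])
            by_weight.setdefault(w, []).append((u, labels[j]))

    included: list[tuple[str, str, float]] = []
    for w in sorted(by_weight):
        # connectivity available strictly below the admission threshold
        H = nx.Graph()
        H.add_nodes_from(labels)
        H.add_edges_from(
            (u, v) for u, v, wi in included if wi < w - epsilon
        )
        if nx.number_connected_components(H) == 1:
            break
        comp = {}
        for cid, members in enumerate(nx.connected_components(H)):
            for node in members:
                comp[node] = cid
        for u, v in by_weight[w]:
            if comp[u] != comp[v]:
                included.append((u, v, w))
    G.add_weighted_edges_from(included)
    return HaploNetwork(G)


def network_clusters(net: HaploNetwork, cut: float) -> dict[str, int]:
    """Assign haplotypes to clusters separated by branches of >= ``cut`` steps.

    Removes every edge with weight >= ``cut`` and labels the remaining
    connected components 1, 2, ... by descending total membership (sum of
    node ``size`` attributes, default 1), ties broken by smallest node label.
    The assignment is also stored on ``net.cluster_id``.
    """
    if cut < 1:
        raise BoundsError("cluster cut must be >= 1")
    H = nx.Graph()
    H.add_nodes_from(net.graph.nodes)
    H.add_edges_from(
        (u, v)
        for u, v, data in net.graph.edges(data=True)
        if data["weight"] < cut
    )
    comps = [
        sorted(members) for members in nx.connected_components(H)
    ]

    def total_size(members: list[str]) -> int:
        return sum(net.graph.nodes[m].get("size", 1) for m in members)

    comps.sort(key=lambda m: (-total_size(m), m[0]))
    assignment = {
        node: cid for cid, members in enumerate(comps, start=1) for node in members
    }
    net.cluster_id = assignment
    return assignment


def catalog_network(
    catalog: HaplotypeCatalog,
    epsilon: float = 0,
    include_interceptions: bool = True,
) -> HaploNetwork:
    """Minimum spanning network over the haplotypes of a catalog.

    Interception-carried haplotypes are included by default (they belong in
    the network even though they are excluded from population statistics);
    haplotypes carried only by the outgroup record are never included — the
    outgroup is a different species and belongs only in the rooted tree.
    Node sizes count analysis members plus, when included, interception
    carriers.
    """
    keep: list = []
    for hap in catalog:
        n_int = sum(1 for s in hap.aux_members.values() if s == "interception")
        size = hap.count + (n_int if include_interceptions else 0)
        if size > 0:
            keep.append((hap, size))
    labels = [h.label for h, _ in keep]
    aln = Alignment(labels, [h.seq for h, _ in keep])
    dist = hamming_matrix(aln)
    attrs = {
        h.label: {"size": size, "group_counts": dict(h.per_group_counts)}
        for h, size in keep
    }
    return minimum_spanning_network(dist, epsilon=epsilon, node_attrs=attrs)
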