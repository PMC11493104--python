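"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from haplotrace import collapse_and_label
from haplotrace.synthetic import alignment_from_counts

# Published per-country haplotype counts for the global survey: four shared
# ("invasive") haplotypes A-D plus country-private haplotypes, 403 specimens
# in 16 countries.  Private haplotype ids are prefixed with the country code.
TABLE2_COUNTS = {
    "Argentina": {"ARp1": 5, "ARp2": 1, "ARp3": 1, "ARp4": 1, "ARp5": 1},
    "Colombia": {"COp1": 15, **{f"COp{i}": 1 for i in range(2, 9)}},
    "Ecuador": {"A": 4, "ECp1": 33, **{f"ECp{i}": 1 for i in range(2, 14)}},
    "Peru": {
        "A": 32, "B": 7, "C": 1, "D": 1,
        "PEp1": 38, **{f"PEp{i}": 1 for i in range(2, 16)},
    },
    "CostaRica": {"A": 15, "CRp1": 1, "CRp2": 1},
    "Guatemala": {"A": 37, "B": 4, "GTp1": 1},
    "Panama": {"A": 7},
    "Canada": {"A": 7, "B": 1, "CAp1": 1},
    "China": {"A": 9},
    "Indonesia": {"A": 8, "B": 4, "IDp1": 5},
    "Israel": {"A": 9, "B": 1, "C": 1, "D": 1, "ILp1": 1},
    "Italy": {"A": 8, "B": 1},
    "Malaysia": {"A": 2},
    "Philippines": {"A": 60},
    "SouthAfrica": {"A": 31},
    "SriLanka": {"A": 14},
}

TABLE2_STATUS = {
    "Argentina": "native",
    "Colombia": "native",
    "Ecuador": "native",
    "Peru": "native",
    "CostaRica": "introduced",
    "Guatemala": "introduced",
    "Panama": "introduced",
    "Canada": "introduced",
    "China": "introduced",
    "Indonesia": "introduced",
    "Israel": "introduced",
    "Italy": "introduced",
    "Malaysia": "introduced",
    "Philippines": "introduced",
    "SouthAfrica": "introduced",
    "SriLanka": "introduced",
}


@pytest.fixture(scope="session")
def table2_dataset():
    """Alignment + metadata + catalog realizing the published count table."""
    aln, meta = alignment_from_counts(TABLE2_COUNTS, TABLE2_STATUS, seed=42)
    catalog = collapse_and_label(aln, meta)
    return aln, meta, catalog


# ---------------------------------------------------------------- oracles --

def msn_oracle(dist) -> set[frozenset]:
    """Union of ALL minimum spanning trees, by exhaustive enumeration.

    Independent of the Kruskal-round construction: iterates spanning trees
    in increasing total weight and unions every tree tied at the minimum.
    """
    G = nx.Graph()
    n = len(dist.ids)
    for i in range(n):
        for j in range(i + 1, n):
            G.add_edge(dist.ids[i], dist.ids[j], weight=float(dist.D[i, j]))

    def tree_weight(T):
        return sum(G[u][v]["weight"] for u, v in T.edges)

    edges: set[frozenset] = set()
    min_w = None
    for T in nx.SpanningTreeIterator(G):
        w = tree_weight(T)
        if min_w is None:
            min_w = w
        if w > min_w + 1e-9:
            break
        edges |= {frozenset(e) for e in T.edges}
    return edges


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive edge lengths.

    Returns ``(taxa, D, true_bipartitions, leaf_lengths, internal_lengths)``
    where ``D`` is the exact path-length (additive) distance matrix,
    ``true_bipartitions`` the set of canonical non-trivial splits,
    ``leaf_lengths`` maps taxon -> pendant edge length and
    ``internal_lengths`` maps bipartition -> internal edge length.
    """
    G = nx.Graph()
    G.add_edge("I0", "T0", weight=rng.uniform(0.5, 2.0))
    G.add_edge("I0", "T1", weight=rng.uniform(0.5, 2.0))
    G.add_edge("I0", "T2", weight=rng.uniform(0.5, 2.0))
    next_int, next_leaf = 1, 3
    while next_leaf < n_taxa:
        u, v = list(G.edges)[rng.integers(0, G.number_of_edges())]
        w = G[u][v]["weight"]
        t = rng.uniform(0.2, 0.8)
        m, leaf = f"I{next_int}", f"T{next_leaf}"
        G.remove_edge(u, v)
        G.add_edge(u, m, weight=w * t)
        G.add_edge(m, v, weight=w * (1 - t))
        G.add_edge(m, leaf, weight=rng.uniform(0.5, 2.0))
        next_int += 1
        next_leaf += 1

    taxa = sorted(x for x in G.nodes if x.startswith("T"))
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    D = np.array([[lengths[a][b] for b in taxa] for a in taxa])

    all_leaves = frozenset(taxa)
    ref = min(all_leaves)
    bips: set[frozenset] = set()
    internal_lengths: dict[frozenset, float] = {}
    for u, v in G.edges:
        H = G.copy()
        H.remove_edge(u, v)
        side = frozenset(
            x for x in nx.node_connected_component(H, u) if x.startswith("T")
        )
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            bips.add(side)
            internal_lengths[side] = G[u][v]["weight"]
    leaf_lengths = {
        t: G[t][next(iter(G[t]))]["weight"] for t in taxa
    }
    return taxa, D, bips, leaf_lengths, internal_lengths
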