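"""Neighbor joining, bootstrap support, rooting and newick serialization."""

import io

import dendropy
import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from conftest import random_additive_tree
from haplotrace.distances import DistanceMatrix, hamming_matrix
from haplotrace.errors import MetadataError, UndefinedStatisticError
from haplotrace.njtree import (
    bootstrap_support,
    neighbor_joining,
    root_with_outgroup,
)
from haplotrace.seqio import Alignment
from haplotrace.synthetic import SimConfig, simulate_dataset


def dmat(ids, D):
    return DistanceMatrix(list(ids), np.asarray(D, dtype=float))


def leaf_lengths(tree):
    return {
        n.label: n.length for n in tree.root.walk() if n.is_leaf
    }


def internal_lengths(tree):
    bips = tree.edge_bipartitions()
    out = {}
    for node in tree.root.walk():
        if id(node) in bips and not node.is_leaf:
            out[bips[id(node)]] = node.length
    return out


FOUR_TAXON = dmat(
    "ABCD",
    [[0, 3, 5, 6],
     [3, 0, 6, 7],
     [5, 6, 0, 7],
     [6, 7, 7, 0]],
)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        tree = neighbor_joining(FOUR_TAXON)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert leaf_lengths(tree) == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        )
        assert internal_lengths(tree)[frozenset({"C", "D"})] == pytest.approx(1.0)

    def test_three_taxon_star_solves_linear_system(self):
        tree = neighbor_joining(dmat("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        assert leaf_lengths(tree) == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})
        assert tree.to_newick() == "(A:1,B:1,C:3);"

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            neighbor_joining(dmat("AB", [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_additive_trees_recovered_with_exact_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa, D, bips, pendant, internal = random_additive_tree(n, rng)
        tree = neighbor_joining(dmat(taxa, D))
        assert tree.bipartitions() == bips
        assert leaf_lengths(tree) == pytest.approx(pendant)
        got_internal = internal_lengths(tree)
        for bip, length in internal.items():
            assert got_internal[bip] == pytest.approx(length)

    def test_negative_length_estimates_clamped_with_annotation(self):
        rng = np.random.default_rng(12)
        found = False
        for _ in range(50):
            n = 5
            D = rng.uniform(0.5, 3.0, (n, n))
            D = np.triu(D, 1)
            D = D + D.T
            tree = neighbor_joining(dmat([f"T{i}" for i in range(n)], D))
            for node in tree.root.walk():
                assert node.length >= 0
                if node.raw_length is not None:
                    assert node.raw_length < 0
                    found = True
        assert found  # random non-additive matrices do produce negatives

    def test_ultrametric_matrix_matches_single_linkage_topology(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            # random ultrametric: coalesce 5 taxa at increasing heights
            n = 5
            taxa = [f"T{i}" for i in range(n)]
            Z = hierarchy.linkage(rng.uniform(0, 1, (n, 2)), method="single")
            D = squareform(hierarchy.cophenet(Z))
            tree = neighbor_joining(dmat(taxa, D))
            # single-linkage merge clusters are exactly the NJ bipartitions
            clusters = {}
            expected = set()
            for k, (a, b, _, _) in enumerate(Z):
                def members_of(x):
                    x = int(x)
                    return clusters[x] if x in clusters else [taxa[x]]

                members = members_of(a) + members_of(b)
                clusters[n + k] = members
                side = frozenset(members)
                if min(taxa) in side:
                    side = frozenset(taxa) - side
                if 2 <= len(side) <= n - 2:
                    expected.add(side)
            assert tree.bipartitions() == expected

    def test_agrees_with_dendropy_on_additive_matrix(self):
        taxa = ["A", "B", "C", "D"]
        csv = "," + ",".join(taxa) + "\n" + "\n".join(
            t + "," + ",".join(str(FOUR_TAXON.D[i, j]) for j in range(4))
            for i, t in enumerate(taxa)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        ours = dendropy.Tree.get(
            data=neighbor_joining(FOUR_TAXON).to_newick(),
            schema="newick",
            taxon_namespace=pdm.taxon_namespace,
        )
        theirs = pdm.nj_tree()
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert (
            dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0
        )


def split_clade_alignment(k_fixed=20, L=200):
    """Two internally resolved 3-leaf clades separated by k fixed differences.

    Within each clade the topology is (X1,(X2,X3)) with distinct positive
    branch lengths, so the NJ tree is fully resolved and tie-free.
    """
    rng = np.random.default_rng(2)
    base = rng.choice(list("ACGT"), L)
    sites = iter(rng.choice(L, k_fixed + 14, replace=False))

    def mutate(arr, k):
        arr = arr.copy()
        for _ in range(k):
            s = next(sites)
            arr[s] = "ACGT"[("ACGT".index(arr[s]) + 1) % 4]
        return arr

    other = mutate(base, k_fixed)
    seqs = {}
    for clade, anc in (("A", base), ("B", other)):
        inner = mutate(anc, 3)
        seqs[f"{clade}1"] = "".join(mutate(anc, 1))
        seqs[f"{clade}2"] = "".join(mutate(inner, 1))
        seqs[f"{clade}3"] = "".join(mutate(inner, 2))
    return Alignment(list(seqs), list(seqs.values()))


class TestBootstrap:
    def test_clear_split_gets_high_support(self):
        aln = split_clade_alignment()
        tree, supports = bootstrap_support(aln, B=100, seed=1)
        split = frozenset({"B1", "B2", "B3"})
        assert supports[split] >= 95

    def test_single_replicate_supports_are_all_or_nothing(self):
        aln = split_clade_alignment()
        _, supports = bootstrap_support(aln, B=1, seed=0)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_supports_invariant_to_leaf_input_order(self):
        aln = split_clade_alignment()
        perm = ["B2", "A1", "B3", "A3", "B1", "A2"]
        aln2 = aln.subset(perm)
        _, s1 = bootstrap_support(aln, B=50, seed=5)
        _, s2 = bootstrap_support(aln2, B=50, seed=5)
        assert set(s1) == set(s2)
        for bip in s1:
            assert abs(s1[bip] - s2[bip]) <= 12  # same splits, resampling noise

    def test_zero_length_internal_edges_flagged(self):
        # an equidistant trio is a polytomy: its arbitrary resolution
        # creates a zero-length internal edge
        L = 60
        base = ["A"] * L
        seqs = {}
        for i, name in enumerate(["A1", "A2", "A3"]):
            arr = base.copy()
            arr[i] = "T"  # one private mutation each
            seqs[name] = "".join(arr)
        far = base.copy()
        for s in range(10, 30):
            far[s] = "G"
        for i, name in enumerate(["B1", "B2"]):
            arr = far.copy()
            arr[30 + i] = "T"
            seqs[name] = "".join(arr)
        star = Alignment(list(seqs), list(seqs.values()))
        tree, _ = bootstrap_support(star, B=10, seed=0)
        flagged = [
            n for n in tree.root.walk()
            if not n.is_leaf and n.zero_length_flag
        ]
        assert flagged


class TestRooting:
    def test_root_bisects_outgroup_pendant_edge(self):
        tree = neighbor_joining(FOUR_TAXON)
        rooted = root_with_outgroup(tree, "D")
        assert rooted.rooted
        og, ingroup = rooted.root.children
        if og.label != "D":
            og, ingroup = ingroup, og
        assert og.label == "D"
        assert og.length == pytest.approx(2.0)  # half of D's pendant edge (4)
        assert og.length == pytest.approx(ingroup.length)

    def test_rooting_preserves_bipartitions(self):
        rng = np.random.default_rng(8)
        taxa, D, bips, _, _ = random_additive_tree(7, rng)
        tree = neighbor_joining(dmat(taxa, D))
        rooted = root_with_outgroup(tree, taxa[0])
        assert rooted.bipartitions() == tree.bipartitions() == bips

    def test_missing_outgroup_rejected(self):
        tree = neighbor_joining(FOUR_TAXON)
        with pytest.raises(MetadataError):
            root_with_outgroup(tree, "Z")

    def test_distant_outgroup_is_first_split(self):
        # outgroup at ~5.6% divergence vs <1% ingroup spread
        cfg = SimConfig(seed=4, n_per_native_pop=(6, 6, 6),
                        n_per_introduced_pop=(6,), include_outgroup=True)
        res = simulate_dataset(cfg)
        hap_ids = sorted(set(res.truth["true_haplotype"]))
        aln = Alignment(hap_ids, [res.hap_seqs[h] for h in hap_ids])
        tree = neighbor_joining(hamming_matrix(aln, normalize=True))
        rooted = root_with_outgroup(tree, "OUTGROUP")
        og = [c for c in rooted.root.children if c.label == "OUTGROUP"]
        assert og and og[0].length > 0.02


class TestNewick:
    def test_round_trip_preserves_bipartitions(self):
        rng = np.random.default_rng(17)
        for seed in range(3):
            taxa, D, bips, _, _ = random_additive_tree(
                int(rng.integers(4, 8)), rng
            )
            tree = neighbor_joining(dmat(taxa, D))
            parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
            parsed.encode_bipartitions()
            got = set()
            all_leaves = frozenset(taxa)
            ref = min(all_leaves)
            for edge in parsed.preorder_edge_iter():
                if edge.head_node and not edge.head_node.is_leaf():
                    side = frozenset(
                        lf.taxon.label for lf in edge.head_node.leaf_iter()
                    )
                    if ref in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        got.add(side)
            assert got == bips

    def test_supports_emitted_only_on_internal_edges(self):
        aln = split_clade_alignment()
        tree, _ = bootstrap_support(aln, B=20, seed=3)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        for leaf in parsed.leaf_node_iter():
            assert leaf.taxon is not None and leaf.taxon.label in set(aln.ids)
        internal_labels = [
            n.label for n in parsed.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert internal_labels  # at least one support rendered
        for lab in internal_labels:
            assert 0 <= float(lab) <= 100
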