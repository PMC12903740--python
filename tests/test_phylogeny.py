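import math

import dendropy
import numpy as np
import pytest

from symred.phylogeny import (
    Alignment, DistanceMatrix, EmptyAlignmentError, Supermatrix, TreeNode,
    align_family, bipartitions, bootstrap_support, build_supermatrix,
    distances, filter_columns, neighbor_joining, robinson_foulds,
)


def random_additive_case(rng, n_taxa):
    """Random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix (oracle independent of NJ)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        a.branch_length = float(rng.uniform(0.1, 1.0))
        b.branch_length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    a, b = nodes
    a.branch_length = float(rng.uniform(0.1, 1.0))
    b.branch_length = float(rng.uniform(0.1, 1.0))
    tree = TreeNode(children=[a, b])

    def leaf_depths(node):
        if node.is_leaf:
            return {node.name: node.branch_length}
        out = {}
        for child in node.children:
            for leaf, d in leaf_depths(child).items():
                out[leaf] = d + node.branch_length
        return out

    dist = {}
    def collect(node):
        below = []
        if node.is_leaf:
            return {node.name: 0.0}
        for child in node.children:
            depths = {l: d + child.branch_length
                      for l, d in collect(child).items()}
            for seen in below:
                for l1, d1 in seen.items():
                    for l2, d2 in depths.items():
                        dist[frozenset((l1, l2))] = d1 + d2
            below.append(depths)
        merged = {}
        for depths in below:
            merged.update(depths)
        return merged

    collect(tree)
    mat = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            mat[i, j] = mat[j, i] = dist[frozenset((taxa[i], taxa[j]))]
    return tree, DistanceMatrix(taxa, mat)


class TestAlignFamily:
    def test_identical_sequences_align_gap_free(self):
        aln = align_family({"a": "MKVLW", "b": "MKVLW", "c": "MKVLW"})
        assert aln.rows == ["MKVLW"] * 3
        assert aln.n_columns == 5

    def test_single_deletion_creates_one_gap_column(self):
        aln = align_family({"a": "MKV", "b": "MV"})
        assert aln.n_columns == 3
        assert aln.row("a") == "MKV"
        assert aln.row("b").count("-") == 1

    def test_input_order_invariance(self):
        seqs = {"a": "MKVLWAALLK", "b": "MKVLWALLK", "c": "MKVIWAALLK"}
        fwd = align_family(seqs)
        rev = align_family(dict(reversed(list(seqs.items()))))
        assert fwd.names == rev.names
        assert fwd.rows == rev.rows

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_family({"a": "MKV"})


class TestFilterColumns:
    def test_clean_alignment_unchanged(self):
        aln = Alignment(["a", "b"], ["M" * 20, "K" * 20])
        assert filter_columns(aln).rows == aln.rows

    def test_gapped_column_removed_and_flanks_reevaluated(self):
        # 12 clean | 1 gapped | 8 clean: right flank is below the minimum
        # block length once the gap splits it, so only the left block stays
        rows = ["A" * 12 + "A" + "A" * 8,
                "C" * 12 + "-" + "C" * 8]
        out = filter_columns(Alignment(["a", "b"], rows))
        assert out.n_columns == 12
        assert out.row("b") == "C" * 12

    def test_alignment_shorter_than_block_is_empty_result(self):
        aln = Alignment(["a", "b"], ["MKVLW", "MKVLW"])
        with pytest.raises(EmptyAlignmentError):
            filter_columns(aln, min_block_length=10)


class TestDistances:
    def make_sm(self, rows):
        return Supermatrix(list(rows), dict(rows))

    def test_identical_rows_zero(self):
        sm = self.make_sm({"a": "M" * 50, "b": "M" * 50, "c": "M" * 50})
        assert distances(sm, "p_distance").get("a", "b") == 0.0

    def test_p_distance_fraction(self):
        sm = self.make_sm({"a": "A" * 100,
                           "b": "C" * 10 + "A" * 90,
                           "c": "A" * 100})
        assert distances(sm, "p_distance").get("a", "b") == pytest.approx(0.10)

    def test_poisson_correction_closed_form(self):
        sm = self.make_sm({"a": "A" * 100,
                           "b": "C" * 10 + "A" * 90,
                           "c": "A" * 100})
        assert distances(sm, "poisson").get("a", "b") == \
            pytest.approx(-math.log(0.9), abs=1e-5)
        assert round(distances(sm, "poisson").get("a", "b"), 5) == 0.10536

    def test_gap_columns_excluded_pairwise(self):
        sm = self.make_sm({"a": "AAAA-AAAAA",
                           "b": "CAAA-AAAAA",
                           "c": "AAAAAAAAAA"})
        assert distances(sm, "p_distance").get("a", "b") == pytest.approx(1 / 9)

    def test_no_comparable_columns_rejected(self):
        sm = self.make_sm({"a": "AA--", "b": "--AA", "c": "AAAA"})
        with pytest.raises(ValueError):
            distances(sm, "p_distance")


class TestNeighborJoining:
    def test_classic_additive_four_taxon_matrix(self):
        # additive matrix of ((a:2,b:3):1,(c:4,d:2)) with central edge 1
        taxa = ["a", "b", "c", "d"]
        mat = np.array([[0, 5, 7, 5],
                        [5, 0, 8, 6],
                        [7, 8, 0, 6],
                        [5, 6, 6, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa, mat))
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        # exact branch lengths recovered for an additive input
        leaf = {n.name: n.branch_length for n in tree.postorder() if n.is_leaf}
        assert leaf == pytest.approx({"a": 2.0, "b": 3.0, "c": 4.0, "d": 2.0})

    def test_three_taxa_closed_form(self):
        taxa = ["a", "b", "c"]
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa, mat))
        leaf = {n.name: n.branch_length for n in tree.postorder() if n.is_leaf}
        assert leaf == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_random_additive_matrices_exact_topology(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            planted, dm = random_additive_case(rng, n)
            inferred = neighbor_joining(dm)
            assert bipartitions(inferred) == bipartitions(planted)

    def test_ultrametric_matrix_matches_upgma_topology(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(23)
        # ultrametric distances from a random UPGMA dendrogram
        points = rng.random((6, 4))
        linkage = hierarchy.linkage(points, method="average")
        cophenetic = hierarchy.cophenet(linkage)
        taxa = [f"t{i}" for i in range(6)]
        dm = DistanceMatrix(taxa, squareform(cophenetic))
        nj_parts = bipartitions(neighbor_joining(dm))

        def upgma_parts(link):
            clusters = {i: {taxa[i]} for i in range(6)}
            parts = set()
            for idx, (l, r, _, _) in enumerate(link):
                merged = clusters[int(l)] | clusters[int(r)]
                clusters[6 + idx] = merged
                if 1 < len(merged) < 5:
                    side = frozenset(merged)
                    if "t0" in side:
                        side = frozenset(set(taxa) - side)
                    parts.add(side)
            return parts

        assert nj_parts == upgma_parts(linkage)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))

    def test_agrees_with_reference_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(41)
        for _ in range(5):
            planted, dm = random_additive_case(rng, 7)
            mine = neighbor_joining(dm)
            ref = skbio_nj(SkbioDM(dm.values, dm.taxa))
            ref_parts = set()
            for node in ref.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(dm.taxa) - 1:
                    if min(dm.taxa) in side:
                        side = frozenset(set(dm.taxa) - side)
                    ref_parts.add(side)
            assert bipartitions(mine) == ref_parts


class TestBootstrap:
    def uniform_sm(self):
        # every column carries the same bipartition signal {a,b} | {c,d,e}
        rows = {"a": "A" * 40, "b": "A" * 40,
                "c": "C" * 40, "d": "C" * 40, "e": "C" * 40}
        return Supermatrix(list(rows), rows)

    def test_uniform_signal_all_supports_100(self):
        tree = bootstrap_support(self.uniform_sm(), n_replicates=50, seed=9,
                                 model="p_distance")
        supports = [n.support for n in tree.postorder() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_fixed_seed_reproducible(self, small_result):
        sm = small_result.supermatrix
        t1 = bootstrap_support(sm, n_replicates=30, seed=4)
        t2 = bootstrap_support(sm, n_replicates=30, seed=4)
        assert t1.newick() == t2.newick()

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self.uniform_sm(), n_replicates=1, seed=2,
                                 model="p_distance")
        supports = {n.support for n in tree.postorder() if n.support is not None}
        assert supports <= {0.0, 100.0}

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.uniform_sm(), n_replicates=0, seed=1)


class TestTreesAndNewick:
    def test_supermatrix_gap_pads_missing_taxa(self):
        aln = Alignment(["a", "b"], ["MKV", "MKV"])
        sm = build_supermatrix({"f1": aln}, ["a", "b", "c"])
        assert sm.rows["c"] == "---"
        assert sm.family_boundaries == {"f1": (0, 3)}

    def test_robinson_foulds_zero_iff_same_splits(self):
        rng = np.random.default_rng(31)
        planted, dm = random_additive_case(rng, 8)
        inferred = neighbor_joining(dm)
        assert robinson_foulds(inferred, planted) == 0

    def test_robinson_foulds_agrees_with_dendropy(self):
        rng = np.random.default_rng(37)
        t1, dm1 = random_additive_case(rng, 7)
        t2, _ = random_additive_case(rng, 7)
        mine = robinson_foulds(t1, t2)
        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.newick(), schema="newick",
                               taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=t2.newick(), schema="newick",
                               taxon_namespace=taxa)
        d1.encode_bipartitions(); d2.encode_bipartitions()
        assert mine == dendropy.calculate.treecompare \
            .symmetric_difference(d1, d2)

    def test_newick_supports_round_trip_through_dendropy(self, small_result):
        tree = dendropy.Tree.get(data=small_result.tree.newick(),
                                 schema="newick")
        labels = [int(n.label) for n in tree.internal_nodes() if n.label]
        assert labels and all(0 <= s <= 100 for s in labels)
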