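"""JC distances, neighbor joining, bootstrap supports and Newick round trips."""

import numpy as np
import pytest

from acidhet import phylo
from acidhet import synthesize as syn
from conftest import make_random_additive_tree


def path_length_matrix(tree, labels):
    """Leaf-to-leaf path lengths of a dendropy tree, ordered by labels."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                tns.get_taxon(labels[i]), tns.get_taxon(labels[j]))
    return d


class TestPDistance:
    def test_identical(self):
        assert phylo.p_distance("ACGT", "ACGT") == 0.0

    def test_single_mismatch(self):
        assert phylo.p_distance("AAAA", "AAAT") == 0.25

    def test_pairwise_deletion(self):
        assert phylo.p_distance("AA-A", "AATA") == 0.0

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            phylo.p_distance("--", "AA")

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            phylo.p_distance("AAA", "AA")


class TestJcDistance:
    def test_zero(self):
        assert phylo.jc_distance(0.0, 4) == 0.0

    def test_protein_hand_value(self):
        assert phylo.jc_distance(0.1, 20) == pytest.approx(0.10566, abs=1e-5)

    def test_nucleotide_hand_value(self):
        assert phylo.jc_distance(0.3, 4) == pytest.approx(-0.75 * np.log(0.6))

    def test_saturation_capped_and_flagged(self):
        assert phylo.is_saturated(0.75, 4)
        assert phylo.jc_distance(0.8, 4, cap=5.0) == 5.0

    def test_strictly_increasing_and_first_order(self):
        ps = np.linspace(0.0, 0.7, 50)
        ds = [phylo.jc_distance(p, 4) for p in ps]
        assert np.all(np.diff(ds) > 0)
        assert phylo.jc_distance(1e-6, 4) == pytest.approx(1e-6, rel=1e-3)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = phylo.neighbor_joining(dm)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxa_additive(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        assert phylo.tree_bipartitions(tree) == {frozenset({"C", "D"})}
        assert np.allclose(path_length_matrix(tree, labels), d)

    def test_equal_distances_star_like(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(list("ABCD"), d))
        internal = [n for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n is not tree.seed_node]
        assert all(n.edge.length == pytest.approx(0.0) for n in internal)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["A", "B"],
                                 np.array([[0, -1], [-1, 0]], float))

    def test_additive_matrices_recovered_exactly(self):
        """NJ reproduces random additive matrices: exact path lengths and the
        same topology as an independent NJ implementation (scikit-bio)."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            _, labels, d = make_random_additive_tree(rng, n)
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
            assert np.allclose(path_length_matrix(tree, labels), d, atol=1e-9)
            sk_tree = sk_nj(SkDM(d, ids=labels))
            assert phylo.tree_bipartitions(tree) == \
                skbio_bipartitions(sk_tree, labels)


def skbio_bipartitions(sk_tree, labels):
    all_labels = frozenset(labels)
    anchor = min(all_labels)
    bips = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            bips.add(side)
    return bips


class TestBootstrap:
    def test_perfect_signal_full_support(self):
        # A,B share one state and C,D another at every column
        seqs = {"A": "AAAA", "B": "AAAA", "C": "TTTT", "D": "TTTT"}
        tree = phylo.bootstrap_support(seqs, alphabet_size=4, n_reps=50,
                                       seed=0)
        internal = [n for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n is not tree.seed_node]
        assert [n.label for n in internal] == ["50"]

    def test_single_replicate_bounds(self):
        rng = np.random.default_rng(1)
        seqs = {lab: "".join(rng.choice(list("ACGT"), 40))
                for lab in "ABCDE"}
        tree = phylo.bootstrap_support(seqs, 4, n_reps=1, seed=3)
        supports = [int(n.label) for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n is not tree.seed_node
                    and n.label is not None]
        assert all(s in (0, 1) for s in supports)

    def test_known_tree_high_support(self):
        """On a 6-taxon tree with long internal edges, every true bipartition
        reaches >= 95/100 bootstrap support at 2000 columns."""
        newick = ("(((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2):0.2,"
                  "E:0.1,F:0.3);")
        seqs = syn.evolve_alignment(
            syn.TreeSimSpec(tree=newick, seq_length=2000, seed=13))
        tree = phylo.bootstrap_support(seqs, 4, n_reps=100, seed=7)
        true_bips = phylo.tree_bipartitions(phylo.read_newick(newick))
        got = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node or node.label is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            all_labels = frozenset(seqs)
            if min(all_labels) in side:
                side = all_labels - side
            got[side] = int(node.label)
        assert set(got) == true_bips
        assert all(v >= 95 for v in got.values())

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        seqs = {lab: "".join(rng.choice(list("ACGT"), 100))
                for lab in "ABCDEF"}
        t1 = phylo.bootstrap_support(seqs, 4, n_reps=20, seed=9)
        t2 = phylo.bootstrap_support(seqs, 4, n_reps=20, seed=9)
        assert phylo.write_newick(t1) == phylo.write_newick(t2)


class TestNewick:
    def test_three_taxon_round_trip(self):
        text = "(A:1.0,B:1.0,C:3.0);"
        tree = phylo.read_newick(text)
        assert phylo.write_newick(tree) == text

    def test_supports_preserved(self):
        text = "((A:1.0,B:2.0)95:0.5,C:1.0,D:1.0);"
        tree = phylo.read_newick(text)
        internal = [n.label for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n is not tree.seed_node]
        assert internal == ["95"]
        assert "95" in phylo.write_newick(tree)

    def test_random_tree_round_trip(self):
        rng = np.random.default_rng(8)
        tree, labels, d = make_random_additive_tree(rng, 10)
        text = phylo.write_newick(tree)
        back = phylo.read_newick(text)
        assert phylo.tree_bipartitions(back) == phylo.tree_bipartitions(tree)
        assert np.allclose(path_length_matrix(back, labels), d, atol=1e-6)

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="[Mm]alformed"):
            phylo.read_newick("((A:1,B:2;")


def test_write_phylip(tmp_path):
    dm = phylo.DistanceMatrix(["A", "B", "C"],
                              np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                       float))
    path = tmp_path / "d.phy"
    phylo.write_phylip(dm, path)
    lines = path.read_text().splitlines()
    assert lines[0].strip() == "3"
    assert lines[1].startswith("A")
    assert "2.000000" in lines[1]


def test_branch_length_recovery_from_simulation():
    """Distances estimated from evolved alignments recover the generating
    path length within 3 SE at 10000 columns."""
    spec = syn.TreeSimSpec(tree="(A:0.2,B:0.3,C:0.1);", seq_length=10000,
                           seed=4)
    seqs = syn.evolve_alignment(spec)
    dm = phylo.alignment_distances(seqs, 4)
    i, j = dm.labels.index("A"), dm.labels.index("B")
    p = phylo.p_distance(seqs["A"], seqs["B"])
    se = np.sqrt(p * (1 - p) / 10000) / (1 - 4 / 3 * p)
    assert abs(dm.d[i, j] - 0.5) < 3 * se
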