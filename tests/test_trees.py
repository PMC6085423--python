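import dendropy
import numpy as np
import pytest

from ribovar.distances import DistanceMatrix
from ribovar.trees import (
    as_newick,
    bootstrap_support,
    nj_tree,
    read_newick,
    upgma_tree,
)


def _dm(d, ids=None):
    d = np.asarray(d, dtype=float)
    ids = ids or [f"t{i}" for i in range(d.shape[0])]
    return DistanceMatrix(ids=tuple(ids), d=d)


def tip_distances(tree):
    """Leaf-to-leaf path lengths keyed by frozenset of labels."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1.label < t2.label:
                out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


def unrooted_splits(tree):
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(labels)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side if anchor not in side else labels - side)
    return splits


def random_additive(rng, n_taxa):
    """Random binary tree -> (ids, additive matrix, splits)."""
    ids = [f"t{i}" for i in range(n_taxa)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = ids[i]
    for edge in tree.preorder_edge_iter():
        edge.length = float(rng.uniform(0.05, 1.0))
    tree.seed_node.edge.length = None
    d = np.zeros((n_taxa, n_taxa))
    td = tip_distances(tree)
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = td[frozenset((ids[i], ids[j]))]
    return ids, d, unrooted_splits(tree)


class TestNeighborJoining:
    def test_four_taxon_additive_round_trip(self):
        # matrix of ((a:1,b:2):1,(c:3,d:4):0.5)
        ids = list("abcd")
        d = np.array([
            [0.0, 3.0, 5.5, 6.5],
            [3.0, 0.0, 6.5, 7.5],
            [5.5, 6.5, 0.0, 7.0],
            [6.5, 7.5, 7.0, 0.0],
        ])
        tree = nj_tree(_dm(d, ids))
        # the single internal split ab|cd (normalised to the side without 'a')
        assert unrooted_splits(tree) == {frozenset("cd")}
        td = tip_distances(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                assert td[frozenset((ids[i], ids[j]))] == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(_dm(d, list("abc")))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_identical_rows_become_zero_length_siblings(self):
        d = np.array([
            [0.0, 0.0, 0.4, 0.4],
            [0.0, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.3],
            [0.4, 0.4, 0.3, 0.0],
        ])
        tree = nj_tree(_dm(d, list("abcd")))
        td = tip_distances(tree)
        assert td[frozenset("ab")] == pytest.approx(0.0)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_random_additive_matrices_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            ids, d, true_splits = random_additive(rng, n_taxa)
            tree = nj_tree(_dm(d, ids))
            assert unrooted_splits(tree) == true_splits
            td = tip_distances(tree)
            for i in range(n_taxa):
                for j in range(i + 1, n_taxa):
                    assert td[frozenset((ids[i], ids[j]))] == pytest.approx(d[i, j])

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        ids, d, _ = random_additive(rng, 7)
        ours = nj_tree(_dm(d, ids))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        their_tree = read_newick(str(theirs), from_string=True)
        assert unrooted_splits(ours) == unrooted_splits(their_tree)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(9)
        ids, d, _ = random_additive(rng, 6)
        perm = rng.permutation(6)
        tree1 = nj_tree(_dm(d, ids))
        tree2 = nj_tree(_dm(d[np.ix_(perm, perm)], [ids[k] for k in perm]))
        assert unrooted_splits(tree1) == unrooted_splits(tree2)
        td1, td2 = tip_distances(tree1), tip_distances(tree2)
        for key in td1:
            assert td1[key] == pytest.approx(td2[key])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            _dm(np.array([[0, 1.0, 2], [1, 0, 3], [2, 3.1, 0]]))


def _coalescent_ultrametric(rng, n):
    """Random ultrametric matrix via sequential pair merging."""
    heights = {}
    clusters = [[i] for i in range(n)]
    d = np.zeros((n, n))
    h = 0.0
    while len(clusters) > 1:
        h += rng.uniform(0.05, 0.3)
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return d


class TestUpgma:
    def test_two_taxa_root_at_half_distance(self):
        tree = upgma_tree(_dm(np.array([[0, 0.1], [0.1, 0]]), ["a", "b"]))
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.05)

    def test_identical_sequences_zero_height(self):
        tree = upgma_tree(_dm(np.zeros((4, 4))))
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ultrametric_input_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        d = _coalescent_ultrametric(rng, n)
        tree = upgma_tree(_dm(d))
        td = tip_distances(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert td[frozenset((f"t{i}", f"t{j}"))] == pytest.approx(d[i, j])

    def test_output_is_ultrametric_for_arbitrary_input(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.01, 0.5, (7, 7))
        d = np.triu(a, 1)
        d = d + d.T
        tree = upgma_tree(_dm(d))
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-12


def _diagnostic_alignment():
    # two 4-taxon clades separated by many invariant diagnostic columns
    block_a = "A" * 500
    block_b = "C" * 500
    seqs = [block_a + "ACGT" * 5, block_a + "AGGT" * 5,
            block_b + "ACGT" * 5, block_b + "ACTT" * 5]
    return seqs, ["a1", "a2", "b1", "b2"]


class TestBootstrap:
    def test_strong_split_gets_full_support(self):
        seqs, ids = _diagnostic_alignment()
        tree = bootstrap_support(seqs, ids=ids, builder="nj", metric="p",
                                 n_reps=50, seed=0)
        internal = [n for n in tree.preorder_internal_node_iter()
                    if n is not tree.seed_node and n.label is not None]
        assert internal and all(n.label == "100" for n in internal)

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(5)]
        tree = bootstrap_support(seqs, ids=list("abcde"), builder="upgma",
                                 metric="p", n_reps=1, seed=0)
        labels = {n.label for n in tree.preorder_internal_node_iter() if n.label}
        assert labels <= {"0", "100"}

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(6)]
        t1 = bootstrap_support(seqs, builder="nj", metric="p", n_reps=30, seed=7)
        t2 = bootstrap_support(seqs, builder="nj", metric="p", n_reps=30, seed=7)
        assert as_newick(t1) == as_newick(t2)

    def test_invalid_replicate_count_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(["ACGT", "ACGA", "AGGA"], n_reps=0)


class TestNewick:
    def test_round_trip_preserves_lengths_and_supports(self, tmp_path):
        seqs, ids = _diagnostic_alignment()
        tree = bootstrap_support(seqs, ids=ids, builder="upgma", metric="p",
                                 n_reps=20, seed=3)
        path = tmp_path / "t.nwk"
        path.write_text(as_newick(tree))
        back = read_newick(path)
        td1 = tip_distances(tree)
        back_td = tip_distances(back)
        for key in td1:
            assert back_td[key] == pytest.approx(td1[key])
        labels = sorted(n.label for n in tree.preorder_internal_node_iter() if n.label)
        back_labels = sorted(
            n.label for n in back.preorder_internal_node_iter() if n.label
        )
        assert labels == back_labels
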