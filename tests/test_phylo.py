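"""phylo: distances, neighbor joining, bootstrap, pairwise identity, rates."""

import numpy as np
import pytest

from gainscan.errors import DomainError
from gainscan.io_formats import Alignment, ProteinSequence
from gainscan.phylo import (
    DistanceMatrix,
    align_pair,
    bipartitions,
    bootstrap_support,
    branch_rate,
    complete_deletion,
    distance_matrix,
    nj_tree,
    rate_ratio,
)

from tests._oracles import least_squares_tree, random_additive_tree


def leaf_lengths(tree):
    return {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


class TestCompleteDeletion:
    def test_gap_free_alignment_is_fixed_point(self):
        aln = Alignment([ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDF")])
        assert complete_deletion(aln) == aln

    def test_gapped_columns_are_removed(self):
        aln = Alignment([ProteinSequence("a", "AC-E"), ProteinSequence("b", "ACDE")])
        out = complete_deletion(aln)
        assert out.n_cols == 3
        assert out.member("a").residues == "ACE"
        assert out.member("b").residues == "ACE"

    def test_error_when_nothing_survives(self):
        aln = Alignment([ProteinSequence("a", "-AC"), ProteinSequence("b", "A-C"),
                         ProteinSequence("c", "AA-")])
        with pytest.raises(DomainError):
            complete_deletion(aln)


class TestDistances:
    def test_identical_members_have_zero_distance(self):
        aln = Alignment([ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDE")])
        dm = distance_matrix(aln, "p")
        assert dm[("a", "b")] == 0.0

    def test_p_distance_hand_count(self):
        aln = Alignment([ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDF")])
        assert distance_matrix(aln, "p")[("a", "b")] == pytest.approx(0.25)

    def test_poisson_correction(self):
        aln = Alignment([ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDF")])
        assert distance_matrix(aln, "poisson")[("a", "b")] == pytest.approx(
            -np.log(0.75), abs=1e-4
        )

    def test_poisson_saturation_names_the_pair(self):
        aln = Alignment([ProteinSequence("a", "AC"), ProteinSequence("b", "CD")])
        with pytest.raises(DomainError, match=r"\(a, b\)"):
            distance_matrix(aln, "poisson")

    def test_poisson_dominates_p_pointwise(self):
        rng = np.random.default_rng(0)
        seqs = [
            ProteinSequence(f"s{i}", "".join(rng.choice(list("ACDEFGHIK"), size=40)))
            for i in range(5)
        ]
        aln = Alignment(seqs)
        p = distance_matrix(aln, "p").d
        poisson = distance_matrix(aln, "poisson").d
        assert (poisson >= p - 1e-12).all()

    def test_x_mismatches_everything_including_itself(self):
        aln = Alignment([ProteinSequence("a", "AXDE"), ProteinSequence("b", "AXDE")])
        assert distance_matrix(aln, "p")[("a", "b")] == pytest.approx(0.25)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        assert leaf_lengths(tree) == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_four_taxon_additive_recovery(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        assert leaf_lengths(tree) == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        )
        labels, dt = patristic(tree)
        assert dt == pytest.approx(d)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(3)
        _, _, d = random_additive_tree(5, rng)
        labels = ["A", "B", "C", "D", "E"]
        t1 = nj_tree(DistanceMatrix(tuple(labels), d))
        perm = [4, 2, 0, 3, 1]
        d2 = d[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix(tuple(labels[i] for i in perm), d2))
        assert bipartitions(t1) == bipartitions(t2)
        assert leaf_lengths(t1) == pytest.approx(leaf_lengths(t2))

    def test_too_few_taxa(self):
        with pytest.raises(DomainError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_matches_least_squares_search_on_additive_matrices(self, n_taxa):
        """On additive input NJ must find the same tree as exhaustive search."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(3 if n_taxa < 6 else 2):
            _, _, d = random_additive_tree(n_taxa, rng)
            labels = tuple(f"L{i}" for i in range(n_taxa))
            tree = nj_tree(DistanceMatrix(labels, d))
            # NJ reproduces the generating matrix exactly
            _, dt = patristic(tree)
            order = np.argsort(labels)  # patristic() sorts labels
            assert dt == pytest.approx(d[np.ix_(order, order)], abs=1e-9)
            # exhaustive least-squares search lands on the same topology
            oracle_bips, sse, _ = least_squares_tree(d)
            assert sse == pytest.approx(0.0, abs=1e-12)
            nj_bips = {
                frozenset(int(lbl[1:]) for lbl in side)
                for side in bipartitions(tree)
            }
            # canonicalize both away from leaf 0
            full = set(range(n_taxa))
            nj_bips = {
                frozenset(s) if 0 not in s else frozenset(full - s) for s in nj_bips
            }
            assert nj_bips == oracle_bips

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(7)
        _, _, d = random_additive_tree(6, rng)
        labels = [f"L{i}" for i in range(6)]
        ours = nj_tree(DistanceMatrix(tuple(labels), d))
        theirs = skbio_tree.nj(SkbioDM(d, ids=labels))
        their_bips = set()
        all_labels = frozenset(labels)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if "L0" in side:
                side = all_labels - side
            if 2 <= len(side) <= len(labels) - 2:
                their_bips.add(side)
        assert bipartitions(ours) == their_bips


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment():
        # two 3-member clades separated by 50 fixed differences
        rng = np.random.default_rng(11)
        shared = "".join(rng.choice(list("ACDEFGHIK"), size=30))
        block_a = "A" * 50
        block_b = "C" * 50
        members = [ProteinSequence(f"A{i}", shared + block_a) for i in range(1, 4)]
        members += [ProteinSequence(f"B{i}", shared + block_b) for i in range(1, 4)]
        # add mild noise so within-clade structure exists
        return Alignment(members)

    def test_overwhelming_signal_gives_full_support(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=5)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        split_support = {
            frozenset(l.taxon.label for l in n.leaf_iter()): float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        }
        # the clade split itself must be fully supported
        assert any(
            s == 100.0
            for side, s in split_support.items()
            if side in (frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3"}))
        )
        assert all(0 <= s <= 100 for s in supports)

    def test_seed_reproducibility(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, n_reps=25, seed=42)
        t2 = bootstrap_support(aln, n_reps=25, seed=42)
        labels1 = [n.label for n in t1.preorder_node_iter() if not n.is_leaf()]
        labels2 = [n.label for n in t2.preorder_node_iter() if not n.is_leaf()]
        assert labels1 == labels2

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=1, seed=0)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)


class TestAlignPair:
    def test_identical_sequences(self):
        a = ProteinSequence("a", "MKVLLE")
        s = align_pair(a, ProteinSequence("b", "MKVLLE"))
        assert s.identity == 100.0
        assert s.similarity == 100.0

    def test_hand_alignment_with_strong_groups(self):
        s = align_pair(ProteinSequence("a", "MKV"), ProteinSequence("b", "MRI"))
        assert s.identity == pytest.approx(100 / 3, abs=0.05)
        assert s.similarity == pytest.approx(100.0)
        assert s.aligned_pairs == 3

    def test_symmetry(self):
        a = ProteinSequence("a", "MKVLLEAGDEWFK")
        b = ProteinSequence("b", "MRILEAGDWFR")
        s1, s2 = align_pair(a, b), align_pair(b, a)
        assert (s1.identity, s1.similarity) == (s2.identity, s2.similarity)

    def test_x_matches_nothing(self):
        s = align_pair(ProteinSequence("a", "MXK"), ProteinSequence("b", "MXK"))
        assert s.identity == pytest.approx(200 / 3, abs=0.05)

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            align_pair(ProteinSequence("a", "M"), ProteinSequence("b", "-"))


class TestRates:
    def test_rate_arithmetic(self):
        est = branch_rate(0.5, 50)
        assert est.rate == pytest.approx(0.01)

    def test_calibrated_ratio_of_unequal_branches(self):
        # a branch twice as long over a tenfold shorter time span is 20x faster
        fast = branch_rate(2.0, 50)
        slow = branch_rate(1.0, 500)
        assert rate_ratio(fast, slow) == pytest.approx(20.0)

    def test_identical_estimates_ratio_one(self):
        r = branch_rate(0.3, 100)
        assert rate_ratio(r, r) == 1.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DomainError):
            branch_rate(1.0, 0)
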