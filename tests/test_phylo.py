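import numpy as np
import pytest
from skbio import DistanceMatrix

from conftest import make_alignment, random_additive_tree
from transintro.io import SpeciesPartition, partition_by_species
from transintro.phylo import (
    _bipartitions,
    bootstrap_support,
    classify_trans_specific,
    has_identical_interspecific_pair,
    jc_distance_matrix,
    neighbor_joining,
)
from transintro.popgen import SaturationError


def tree_splits(tree, reference):
    """Bipartitions canonicalised as the side not containing `reference`."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for bp in _bipartitions(tree):
        out.add(bp if reference not in bp else tips - bp)
    return out


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = make_alignment([("a", "ACGT" * 5), ("b", "ACGT" * 5), ("c", "ACGT" * 5)])
        dm = jc_distance_matrix(aln)
        assert np.allclose(dm.data, 0.0)

    def test_symmetry_and_zero_diagonal(self, five_taxon_alignment):
        dm = jc_distance_matrix(five_taxon_alignment)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)

    def test_closed_form_distance(self):
        s1 = "A" * 100
        s2 = "T" * 5 + "A" * 95
        aln = make_alignment([("a", s1), ("b", s2), ("c", s1)])
        dm = jc_distance_matrix(aln)
        assert dm["a", "b"] == pytest.approx(0.051744, abs=1e-6)

    def test_pairwise_deletion(self):
        # 5 mismatches over 95 shared called sites for (a, b)
        s1 = "N" * 5 + "A" * 95
        s2 = "T" * 10 + "A" * 90
        aln = make_alignment([("a", s1), ("b", s2), ("c", s2)])
        dm = jc_distance_matrix(aln)
        p = 5 / 95
        assert dm["a", "b"] == pytest.approx(-0.75 * np.log(1 - 4 * p / 3))

    def test_saturated_pair_named_in_error(self):
        aln = make_alignment([("a", "A" * 8), ("b", "T" * 8), ("c", "A" * 8)])
        with pytest.raises(SaturationError, match="a, b"):
            jc_distance_matrix(aln)


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        D, names, want = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(D, names))
        assert tree_splits(tree, names[0]) == want

    def test_three_taxon_closed_form(self):
        # d(ab)=3, d(ac)=4, d(bc)=5 -> limbs a=1, b=2, c=3
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                            ["a", "b", "c"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, list("abcd"))
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert str(t1) == str(t2)

    def test_negative_branches_clamped(self):
        # strongly non-additive matrix that would yield a negative NJ branch
        d = np.array([[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]], float)
        d[0, 2] = d[2, 0] = 8.0
        tree = neighbor_joining(DistanceMatrix(d, list("abcd")))
        for node in tree.postorder():
            if node.length is not None:
                assert node.length >= 0

    def test_nonfinite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(d, list("abc"), validate=False))


class TestBootstrap:
    def test_clean_signal_full_support(self):
        def seq(block, private_site):
            s = list(block + "C" * 50)
            s[private_site] = "G"
            return "".join(s)

        # ten diagnostic sites for the single internal edge, one private
        # mutation per taxon to break ties
        aln = make_alignment([("a1", seq("A" * 10, 20)), ("a2", seq("A" * 10, 25)),
                              ("b1", seq("T" * 10, 30)), ("b2", seq("T" * 10, 35))])
        tree = bootstrap_support(aln, n_boot=100, seed=0)
        supports = [n.support for n in tree.postorder()
                    if not n.is_tip() and getattr(n, "support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_in_range_and_deterministic(self, five_taxon_alignment):
        t1 = bootstrap_support(five_taxon_alignment, n_boot=50, seed=7)
        t2 = bootstrap_support(five_taxon_alignment, n_boot=50, seed=7)

        def sups(t):
            return sorted((frozenset(x.name for x in n.tips()), n.support)
                          for n in t.postorder()
                          if not n.is_tip() and getattr(n, "support", None) is not None)

        assert sups(t1) == sups(t2)
        assert all(0.0 <= s <= 100.0 for _, s in sups(t1))

    def test_identical_sequences_no_informative_bipartitions(self):
        aln = make_alignment([(f"s{i}", "ACGT" * 4) for i in range(4)])
        tree = bootstrap_support(aln, n_boot=20, seed=1)
        assert tree.count(tips=True) == 4


def _make_part(pairs, lyr, hal, out=()):
    aln = make_alignment(pairs)
    ids = [p[0] for p in pairs]
    return aln, SpeciesPartition(aln, tuple(ids.index(x) for x in lyr),
                                 tuple(ids.index(x) for x in hal),
                                 tuple(ids.index(x) for x in out))


class TestTransSpecificCall:
    def test_interleaved_species_is_trans_specific(self, five_taxon_alignment, sheet5):
        # L1 pairs with H1 and L2 with H2 on the tree
        base = five_taxon_alignment.sequences[0][1]

        def mut(s, pos, b):
            s = list(s)
            for p in pos:
                s[p] = b
            return "".join(s)

        aln = make_alignment([
            ("L1", base), ("H1", mut(base, [19], "T")),
            ("L2", mut(base, [0, 1, 2], "T")), ("H2", mut(base, [0, 1, 2, 18], "T")),
            ("OUT", mut(base, [5, 6, 7, 10, 11], "T")),
        ])
        part = partition_by_species(aln, sheet5)
        call = classify_trans_specific(neighbor_joining(jc_distance_matrix(aln)), part)
        assert call.is_trans_specific
        assert not call.lyrata_monophyletic and not call.halleri_monophyletic
        assert call.rooting_used == "OUT"

    def test_reciprocally_monophyletic_is_not(self, five_taxon_alignment, sheet5):
        part = partition_by_species(five_taxon_alignment, sheet5)
        call = classify_trans_specific(
            neighbor_joining(jc_distance_matrix(five_taxon_alignment)), part)
        assert not call.is_trans_specific

    def test_singleton_species_counts_as_monophyletic(self):
        base = "A" * 12 + "C" * 12
        aln, part = _make_part(
            [("L1", base), ("L2", base[:-1] + "T"),
             ("H1", "T" * 4 + base[4:]),
             ("OUT", "A" * 12 + "G" * 12)],
            lyr=["L1", "L2"], hal=["H1"], out=["OUT"])
        call = classify_trans_specific(neighbor_joining(jc_distance_matrix(aln)), part)
        assert call.halleri_monophyletic
        assert not call.is_trans_specific

    def test_midpoint_rooting_without_outgroup(self):
        blockA = "A" * 20 + "C" * 20
        blockB = "T" * 20 + "C" * 20
        aln, part = _make_part(
            [("L1", blockA), ("L2", blockA[:-1] + "G"),
             ("H1", blockB), ("H2", blockB[:-1] + "G")],
            lyr=["L1", "L2"], hal=["H1", "H2"])
        call = classify_trans_specific(neighbor_joining(jc_distance_matrix(aln)), part)
        assert call.rooting_used == "midpoint"
        assert not call.is_trans_specific

    def test_invariant_to_leaf_order(self, sheet5):
        base = "A" * 12 + "C" * 12

        def mut(s, pos, b):
            s = list(s)
            for p in pos:
                s[p] = b
            return "".join(s)

        rows = [("L1", base), ("H1", mut(base, [23], "T")),
                ("L2", mut(base, [0, 1, 2], "T")), ("H2", mut(base, [0, 1, 2, 22], "T")),
                ("OUT", mut(base, [5, 6, 7], "G"))]
        calls = []
        for perm in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            aln = make_alignment([rows[i] for i in perm])
            part = partition_by_species(aln, sheet5)
            calls.append(classify_trans_specific(
                neighbor_joining(jc_distance_matrix(aln)), part).is_trans_specific)
        assert len(set(calls)) == 1

    def test_species_with_no_leaves_rejected(self):
        aln, part = _make_part([("L1", "ACGT"), ("L2", "ACGA"), ("L3", "ACGC")],
                               lyr=["L1", "L2", "L3"], hal=[])
        with pytest.raises(ValueError):
            classify_trans_specific(neighbor_joining(jc_distance_matrix(aln)), part)


class TestIdenticalPair:
    def test_shared_haplotype_detected(self):
        aln, part = _make_part([("L1", "ACGTACGTAC"), ("H1", "ACGTACGTAC"),
                                ("H2", "ACGTACGTAA")], lyr=["L1"], hal=["H1", "H2"])
        assert has_identical_interspecific_pair(part)

    def test_all_pairs_differ(self):
        aln, part = _make_part([("L1", "ACGTACGTAC"), ("H1", "ACGTACGTAA")],
                               lyr=["L1"], hal=["H1"])
        assert not has_identical_interspecific_pair(part)

    def test_low_overlap_identity_rejected(self):
        # pair agrees at every co-called site but shares only 40% of the locus
        s1 = "ACGT" + "N" * 6
        s2 = "ACGT" + "N" * 6
        aln, part = _make_part([("L1", s1), ("H1", s2)], lyr=["L1"], hal=["H1"])
        assert not has_identical_interspecific_pair(part, min_overlap=0.9)
        assert has_identical_interspecific_pair(part, min_overlap=0.3)
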