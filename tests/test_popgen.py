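import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment
from transintro.io import partition_by_species
from transintro.popgen import (
    CODON_TABLE,
    STOP_CODONS,
    SaturationError,
    _CodonProfiles,
    classify_polymorphisms,
    count_haplotypes,
    divergence_extremes,
    incompatible_intervals,
    jukes_cantor,
    min_recombination_events,
    nei_gojobori_pair,
    pairwise_diversity,
    pairwise_raw_distance,
    segregating_sites,
    summarize_gene_class,
)

NONSTOP = sorted(set(CODON_TABLE) - STOP_CODONS)


class TestJukesCantor:
    def test_identity_case(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form_value(self):
        assert jukes_cantor(0.05) == pytest.approx(-0.75 * math.log(1 - 4 * 0.05 / 3),
                                                   abs=1e-12)
        assert jukes_cantor(0.05) == pytest.approx(0.051744, abs=1e-6)

    @pytest.mark.parametrize("p", [0.75, 0.9, -0.01])
    def test_saturation_and_domain(self, p):
        with pytest.raises(SaturationError):
            jukes_cantor(p)

    @given(st.floats(0.0, 0.7), st.floats(0.0, 0.7))
    @settings(max_examples=50, derandomize=True)
    def test_increasing_and_dominates_identity(self, p, q):
        assert jukes_cantor(p) >= p
        if p < q:
            assert jukes_cantor(p) < jukes_cantor(q)


class TestSiteCounts:
    def test_segregating_sites_examples(self):
        assert segregating_sites(["ACT", "ACT", "ACT"]) == 0
        assert segregating_sites(["AAT", "AAA", "ACA"]) == 2
        assert segregating_sites(["A-T", "AAT"]) == 0  # missing ignored

    def test_segregating_requires_two_sequences(self):
        with pytest.raises(ValueError):
            segregating_sites(["ACT"])

    def test_haplotype_counts(self):
        assert count_haplotypes(["AAT"] * 3) == 1
        assert count_haplotypes(["AAT", "AAA", "ACA"]) == 3
        assert count_haplotypes(["AAT", "AAT", "ACA"]) == 2
        with pytest.raises(ValueError):
            count_haplotypes([])


def oracle_pathway_diffs(c1, c2):
    """Exhaustive enumeration of minimal substitution pathways between codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results, blocked = [], []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, bad = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                bad = True
            syn += CODON_TABLE[nxt] == CODON_TABLE[cur]
            nonsyn += CODON_TABLE[nxt] != CODON_TABLE[cur]
            cur = nxt
        (blocked if bad else results).append((syn, nonsyn))
    use = results or blocked
    return (sum(r[0] for r in use) / len(use), sum(r[1] for r in use) / len(use))


class TestNeiGojobori:
    def test_atg_has_no_synonymous_sites(self):
        ss, ns, sd, nd = nei_gojobori_pair(["ATG"], ["ATG"])
        assert (ss, ns, sd, nd) == (0.0, 3.0, 0.0, 0.0)

    def test_phe_third_position(self):
        ss, ns, sd, nd = nei_gojobori_pair(["TTT"], ["TTC"])
        # one third of the third position is synonymous in both Phe codons
        assert ss == pytest.approx(1 / 3)
        assert ns == pytest.approx(3 - 1 / 3)
        assert (sd, nd) == (1.0, 0.0)

    def test_multi_difference_pathway_averaging(self):
        for c1, c2 in [("TTT", "GTA"), ("TTA", "CTG"), ("ATG", "TGG"), ("AAA", "CCC")]:
            ss, ns, sd, nd = nei_gojobori_pair([c1], [c2])
            osd, ond = oracle_pathway_diffs(c1, c2)
            assert sd == pytest.approx(osd)
            assert nd == pytest.approx(ond)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="codon index 1"):
            nei_gojobori_pair(["ATG", "TAA"], ["ATG", "TAA"])

    def test_missing_codons_skipped(self):
        ss, ns, sd, nd = nei_gojobori_pair(["ATG", "A-G"], ["ATG", "ATG"])
        assert ss + ns == pytest.approx(3.0)  # only the clean codon counted

    @given(st.lists(st.sampled_from(NONSTOP), min_size=1, max_size=6),
           st.integers(0, 2**30))
    @settings(max_examples=60, derandomize=True)
    def test_site_conservation_and_diff_count(self, codons1, seed):
        rng = np.random.default_rng(seed)
        codons2 = [NONSTOP[int(rng.integers(len(NONSTOP)))] for _ in codons1]
        ss, ns, sd, nd = nei_gojobori_pair(codons1, codons2)
        assert ss + ns == pytest.approx(3 * len(codons1))
        hamming = sum(a != b for c1, c2 in zip(codons1, codons2)
                      for a, b in zip(c1, c2))
        assert sd + nd == pytest.approx(hamming)

    def test_fast_profile_path_matches_reference(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(NONSTOP[int(rng.integers(len(NONSTOP)))] for _ in range(15))
                for _ in range(4)]
        aln = make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        prof = _CodonProfiles(aln, range(4))
        for i, j in itertools.combinations(range(4), 2):
            ref = nei_gojobori_pair(aln.codon_strings(i), aln.codon_strings(j))
            fast = prof.pair(i, j)
            assert fast == pytest.approx(ref)

    def test_agrees_with_biopython_ng86(self):
        """Independent cross-check of dN/dS components against Bio.codonalign."""
        from Bio import SeqIO
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(5)
        s1 = "".join(NONSTOP[int(rng.integers(len(NONSTOP)))] for _ in range(40))
        # mutate a few positions, avoiding stops
        s2 = list(s1)
        for _ in range(6):
            while True:
                pos = int(rng.integers(len(s2)))
                old = s2[pos]
                s2[pos] = "ACGT"[int(rng.integers(4))]
                cod = "".join(s2[3 * (pos // 3): 3 * (pos // 3) + 3])
                if cod not in STOP_CODONS:
                    break
                s2[pos] = old
        s2 = "".join(s2)
        dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
        ss, ns, sd, nd = nei_gojobori_pair(
            [s1[i:i + 3] for i in range(0, len(s1), 3)],
            [s2[i:i + 3] for i in range(0, len(s2), 3)],
        )
        my_ds = jukes_cantor(sd / ss)
        my_dn = jukes_cantor(nd / ns)
        assert my_ds == pytest.approx(ds, abs=2e-3)
        assert my_dn == pytest.approx(dn, abs=2e-3)


def oracle_min_disjoint_cover(intervals):
    """Exact maximum number of pairwise-disjoint open intervals.

    Dynamic programming over intervals sorted by right endpoint (interval
    scheduling), independent of the reduction+greedy production code path.
    """
    ivs = sorted(set(intervals), key=lambda iv: iv[1])
    best_upto = [0] * (len(ivs) + 1)
    for k, (left, right) in enumerate(ivs, start=1):
        # last interval ending at or before this one's left endpoint
        prev = 0
        for j in range(k - 1, 0, -1):
            if ivs[j - 1][1] <= left:
                prev = j
                break
        best_upto[k] = max(best_upto[k - 1], 1 + best_upto[prev])
    return best_upto[len(ivs)]


class TestMinRecombination:
    def test_compatible_alignment(self):
        assert min_recombination_events(["AAT", "AAA", "ACA"]) == 0

    def test_four_gamete_pair(self):
        assert min_recombination_events(["AA", "AT", "TA", "TT"]) == 1

    def test_missing_data_excludes_site(self):
        # site 0 has a missing value -> excluded, no incompatible pair left
        assert min_recombination_events(["-A", "AT", "TA", "TT"]) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 8, 10
        mat = rng.choice(list("AT"), size=(n, L))
        seqs = ["".join(r) for r in mat]
        assert segregating_sites(seqs) <= 10
        ivs = incompatible_intervals(seqs)
        assert min_recombination_events(seqs) == oracle_min_disjoint_cover(ivs)

    def test_rm_bounded_by_segregating_sites(self):
        rng = np.random.default_rng(99)
        mat = rng.choice(list("ACGT"), size=(6, 20), p=[0.7, 0.1, 0.1, 0.1])
        seqs = ["".join(r) for r in mat]
        assert min_recombination_events(seqs) <= segregating_sites(seqs)


class TestPairwiseDiversity:
    def test_identical_sequences_zero(self):
        aln = make_alignment([("a", "TTTGGG"), ("b", "TTTGGG")])
        for sel in ("all", "synonymous", "nonsynonymous"):
            assert pairwise_diversity(aln, [0, 1], sel) == 0.0

    def test_single_difference_closed_form(self):
        L = 300
        s1 = "ATG" * (L // 3)
        s2 = s1[:-1] + "A"  # ATG -> ATA at the final codon
        aln = make_alignment([("a", s1), ("b", s2)])
        assert pairwise_diversity(aln, [0, 1], "all") == \
            pytest.approx(jukes_cantor(1 / L))

    def test_synonymous_change_hits_pi_s_only(self):
        s1 = "TTT" + "GGG" * 99
        s2 = "TTC" + "GGG" * 99
        aln = make_alignment([("a", s1), ("b", s2)])
        assert pairwise_diversity(aln, [0, 1], "synonymous") > 0
        assert pairwise_diversity(aln, [0, 1], "nonsynonymous") == 0.0

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, derandomize=True)
    def test_two_sequence_pi_total_equals_jc_of_p(self, seed):
        rng = np.random.default_rng(seed)
        base = [NONSTOP[int(rng.integers(len(NONSTOP)))] for _ in range(20)]
        other = list(base)
        for k in rng.integers(0, 20, size=3):
            other[k] = NONSTOP[int(rng.integers(len(NONSTOP)))]
        aln = make_alignment([("a", "".join(base)), ("b", "".join(other))])
        d = pairwise_raw_distance("".join(base), "".join(other))
        assert pairwise_diversity(aln, [0, 1], "all") == pytest.approx(d.d_jc)


class TestPolymorphismPartition:
    def _part(self, lyr, hal):
        pairs = [(f"L{i}", s) for i, s in enumerate(lyr)] + \
                [(f"H{i}", s) for i, s in enumerate(hal)]
        aln = make_alignment(pairs)
        from transintro.io import SpeciesPartition
        return SpeciesPartition(aln, tuple(range(len(lyr))),
                                tuple(range(len(lyr), len(lyr) + len(hal))))

    def test_fixed_site(self):
        pp = classify_polymorphisms(self._part(["AAA", "AAA"], ["TAA", "TAA"]))
        assert (pp.n_fixed, pp.n_shared, pp.n_private_A, pp.n_private_B) == (1, 0, 0, 0)

    def test_shared_site(self):
        pp = classify_polymorphisms(self._part(["AAA", "TAA"], ["AAA", "TAA"]))
        assert pp.n_shared == 1 and pp.n_fixed == 0

    def test_private_sites(self):
        pp = classify_polymorphisms(self._part(["AAA", "TAA"], ["AAA", "AAA"]))
        assert (pp.n_private_A, pp.n_private_B) == (1, 0)

    def test_site_missing_in_one_species_excluded(self):
        pp = classify_polymorphisms(self._part(["-AA", "-AA"], ["TAA", "TAA"]))
        assert pp.n_analyzed == 2

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, derandomize=True)
    def test_categories_mutually_exclusive(self, seed):
        rng = np.random.default_rng(seed)
        lyr = ["".join(rng.choice(list("AT-"), size=12)) for _ in range(4)]
        hal = ["".join(rng.choice(list("AT-"), size=12)) for _ in range(3)]
        pp = classify_polymorphisms(self._part(lyr, hal))
        assert pp.n_fixed + pp.n_shared + pp.n_private_A + pp.n_private_B \
            <= pp.n_analyzed <= 12


class TestDivergenceExtremes:
    def test_identical_across_species_all_zero(self, sheet5):
        aln = make_alignment([("L1", "TTTGGG"), ("L2", "TTTGGG"),
                              ("H1", "TTTGGG"), ("H2", "TTTGGG")])
        from transintro.io import SpeciesPartition
        part = SpeciesPartition(aln, (0, 1), (2, 3))
        ext = divergence_extremes(part)
        assert ext.Ks_L == ext.Ks_H == ext.Kn_L == ext.Kn_H == 0.0

    def test_single_pair_degenerate(self):
        # one synonymous difference over 10 codons: pS well below saturation
        s1 = "TTT" + "GGG" * 9
        s2 = "TTC" + "GGG" * 9
        aln = make_alignment([("L1", s1), ("H1", s2)])
        from transintro.io import SpeciesPartition
        part = SpeciesPartition(aln, (0,), (1,))
        ext = divergence_extremes(part)
        assert ext.Ks_L == ext.Ks_H > 0
        assert ext.Kn_L == ext.Kn_H == 0.0

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(17)
        base = [NONSTOP[int(rng.integers(len(NONSTOP)))] for _ in range(30)]
        seqs = []
        for _ in range(5):
            cods = list(base)
            for k in rng.integers(0, 30, size=4):
                cods[k] = NONSTOP[int(rng.integers(len(NONSTOP)))]
            seqs.append("".join(cods))
        aln = make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        from transintro.io import SpeciesPartition
        part = SpeciesPartition(aln, (0, 1, 2), (3, 4))
        ext = divergence_extremes(part)
        ks_all, kn_all = [], []
        for i in (0, 1, 2):
            for j in (3, 4):
                ss, ns, sd, nd = nei_gojobori_pair(aln.codon_strings(i),
                                                   aln.codon_strings(j))
                ks_all.append(jukes_cantor(sd / ss))
                kn_all.append(jukes_cantor(nd / ns))
        assert ext.Ks_L == pytest.approx(min(ks_all))
        assert ext.Ks_H == pytest.approx(max(ks_all))
        assert ext.Kn_L == pytest.approx(min(kn_all))
        assert ext.Kn_H == pytest.approx(max(kn_all))


class TestGeneClassSummary:
    def test_constant_values_degenerate_ci(self):
        s = summarize_gene_class([0.02] * 5, n_boot=200, seed=1)
        assert s["mean"] == s["ci_low"] == s["ci_high"] == 0.02

    def test_two_locus_mean(self):
        assert summarize_gene_class([0.01, 0.03], n_boot=100, seed=1)["mean"] == \
            pytest.approx(0.02)

    def test_single_locus_ci_flagged_undefined(self):
        s = summarize_gene_class([0.01], seed=1)
        assert s["mean"] == 0.01 and not s["ci_defined"]

    def test_bootstrap_reproducible_under_seed(self):
        vals = np.random.default_rng(3).random(10).tolist()
        a = summarize_gene_class(vals, n_boot=500, seed=42)
        b = summarize_gene_class(vals, n_boot=500, seed=42)
        assert a == b
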