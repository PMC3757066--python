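"""Restriction digestion, RFLP markers, genotype calls, segregation chi-square."""

import numpy as np
import pytest

from concestor.rflp import (
    BSTXI,
    HETEROZYGOUS,
    HOMOZYGOUS_A,
    HOMOZYGOUS_B,
    NO_CALL,
    RestrictionEnzyme,
    call_genotype,
    digest,
    find_enzyme_sites,
    rflp_discover,
    segregation_test,
)
from concestor.seq_io import SequenceRecord

from .oracles import naive_motif_scan


def bstxi_amplicon(cut_at: int, total: int) -> str:
    """All-A amplicon with a single BstXI site placed so the cut falls at ``cut_at``."""
    start = cut_at - BSTXI.cut_offset_top
    site = "CCA" + "GGGGGG" + "TGG"
    seq = "A" * start + site + "A" * (total - start - len(site))
    assert len(seq) == total
    return seq


class TestFindSites:
    def test_literal_match(self):
        assert find_enzyme_sites("CCAGGTACCTGG", BSTXI) == [0]

    def test_no_sites(self):
        assert find_enzyme_sites("AAAA", BSTXI) == []

    def test_bstxi_pattern_is_its_own_reverse_complement(self):
        assert BSTXI.is_palindromic

    def test_matches_naive_oracle_on_random_sequence(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        got = find_enzyme_sites(seq, BSTXI)
        expect = sorted({s for s, _, _ in naive_motif_scan(seq, BSTXI.recognition)})
        assert got == expect

    def test_non_palindromic_enzyme_scans_both_orientations(self):
        # BsaI-like: GGTCTC is not its own reverse complement (rc = GAGACC)
        bsai = RestrictionEnzyme("BsaI", "GGTCTC", 1)
        seq = "AAGGTCTCAAAGAGACCAA"
        #       ^fwd at 2        ^rc at 11
        assert find_enzyme_sites(seq, bsai) == [2, 11]


class TestDigest:
    def test_site_free_sequence_is_one_fragment(self):
        res = digest("A" * 50, BSTXI)
        assert res.lengths == (50,)
        assert res.fragments[0] == "A" * 50

    def test_printed_marker_amplicon_fragments(self):
        """381-bp amplicon with one BstXI site cut at 235 gives 235 + 146."""
        res = digest(bstxi_amplicon(cut_at=235, total=381), BSTXI)
        assert res.lengths == (235, 146)

    def test_two_sites_three_fragments_conserve_length(self):
        seq = bstxi_amplicon(100, 200) + bstxi_amplicon(50, 150)
        res = digest(seq, BSTXI)
        assert len(res.fragments) == 3
        assert sum(res.lengths) == len(seq)
        assert "".join(res.fragments) == seq

    def test_length_conservation_on_random_sequences(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 800))))
            res = digest(seq, BSTXI)
            assert sum(res.lengths) == len(seq)
            assert "".join(res.fragments) == seq


class TestRFLPDiscovery:
    def amplicons(self):
        cut = SequenceRecord("Light1", bstxi_amplicon(235, 381))
        uncut = SequenceRecord("Dark1", "A" * 381)
        return cut, uncut

    def test_cut_versus_uncut_marker(self):
        cut, uncut = self.amplicons()
        markers = rflp_discover(cut, uncut, [BSTXI])
        assert len(markers) == 1
        m = markers[0]
        assert sorted(m.pattern_a) == [146, 235]
        assert m.pattern_b == (381,)

    def test_identical_alleles_no_marker(self):
        cut, _ = self.amplicons()
        other = SequenceRecord("copy", cut.residues)
        assert rflp_discover(cut, other, [BSTXI]) == []

    def test_substitution_destroying_site_splits_pattern(self):
        cut, _ = self.amplicons()
        broken = SequenceRecord("broken", cut.residues.replace("CCA", "ACA", 1))
        markers = rflp_discover(cut, broken, [BSTXI])
        assert len(markers) == 1
        (whole,) = markers[0].pattern_b
        assert whole == 381
        a, b = sorted(markers[0].pattern_a)
        assert a + b == whole


class TestGenotypeCalls:
    def marker(self):
        cut, uncut = SequenceRecord("L", bstxi_amplicon(235, 381)), SequenceRecord("D", "A" * 381)
        return rflp_discover(cut, uncut, [BSTXI])[0]

    def test_parental_and_heterozygous_patterns(self):
        m = self.marker()
        assert call_genotype([235, 146], m) == HOMOZYGOUS_A
        assert call_genotype([381], m) == HOMOZYGOUS_B
        assert call_genotype([381, 235, 146], m) == HETEROZYGOUS

    def test_unexpected_pattern_is_no_call(self):
        m = self.marker()
        assert call_genotype([300, 81], m) == NO_CALL

    def test_simulated_f2_individuals_always_consistent(self):
        """Every digest of a two-haplotype genotype maps back to the truth."""
        m = self.marker()
        hapl = {
            "A": tuple(sorted(m.pattern_a)),
            "B": tuple(sorted(m.pattern_b)),
        }
        truth_to_call = {
            ("A", "A"): HOMOZYGOUS_A,
            ("A", "B"): HETEROZYGOUS,
            ("B", "A"): HETEROZYGOUS,
            ("B", "B"): HOMOZYGOUS_B,
        }
        rng = np.random.default_rng(4)
        for _ in range(200):
            g = (
                "AB"[int(rng.integers(0, 2))],
                "AB"[int(rng.integers(0, 2))],
            )
            observed = sorted(set(hapl[g[0]] + hapl[g[1]]))
            # the gel shows the union of band sizes; rebuild the multiset
            multiset = sorted(hapl[g[0]]) if g[0] == g[1] else sorted(hapl[g[0]] + hapl[g[1]])
            assert call_genotype(multiset, m) == truth_to_call[g]
            assert observed  # bands always visible


class TestSegregationTest:
    def test_exact_fit(self):
        res = segregation_test((25, 50, 25), (1, 2, 1))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_near_mendelian_counts(self):
        """The study-style F2 counts fit 1:2:1 closely."""
        res = segregation_test((25, 54, 23), (1, 2, 1))
        assert res.chi_square == pytest.approx(0.43137, abs=1e-4)
        assert res.p_value == pytest.approx(0.80596, abs=1e-4)

    def test_gross_departure(self):
        res = segregation_test((50, 50, 0), (1, 2, 1))
        assert res.chi_square == pytest.approx(50.0)
        assert res.p_value == pytest.approx(1.39e-11, rel=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            segregation_test((5,), (1,))
        with pytest.raises(ValueError):
            segregation_test((0, 0), (1, 1))
        with pytest.raises(ValueError):
            segregation_test((5, 5), (1, 0))
        with pytest.raises(ValueError):
            segregation_test((5, 5, 5), (1, 1))
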