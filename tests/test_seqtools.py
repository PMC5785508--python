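"""ORF finding, translation, molecular weight, motifs, alignment."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from ifacecons.io_formats import SeqRecord
from ifacecons.seqtools import (PairwiseAlignment, RESIDUE_MASS_DA,
                                WATER_MASS_DA, align_pair, brute_force_score,
                                find_orf, molecular_weight, percent_identity,
                                scan_motif, translate)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def prot(seq, id="p"):
    return SeqRecord(id=id, seq=seq, moltype="protein")


def dna(seq, id="d"):
    return SeqRecord(id=id, seq=seq, moltype="dna")


class TestOrf:
    @pytest.mark.parametrize("seq,start,length,protein", [
        ("ATGAAATAGGG", 0, 6, "MK"),
        ("CCATGTGA", 2, 3, "M"),
        # two ORFs: the longer wins regardless of order
        ("ATGTAACCCATGAAAAAATGA", 9, 9, "MKK"),
    ])
    def test_longest_atg_to_stop(self, seq, start, length, protein):
        orf = find_orf(dna(seq))
        assert (orf.start, orf.length_nt, orf.protein.seq) == (start, length, protein)

    def test_no_orf_errors(self):
        with pytest.raises(ValueError, match="no ATG"):
            find_orf(dna("CCCCCCCCC"))

    def test_length_invariant(self):
        orf = find_orf(dna("GGATGAAACCCGGGTAAGG"))
        assert orf.length_nt == 3 * len(orf.protein.seq)
        assert orf.protein.seq.startswith("M")

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet=AA20.replace("M", ""), min_size=1, max_size=40))
    def test_roundtrip_protein_to_codons(self, tail):
        """Back-translating M + tail + stop and re-finding the ORF recovers it."""
        codon = {aa: c for c, aa in [
            ("GCT", "A"), ("TGT", "C"), ("GAT", "D"), ("GAA", "E"), ("TTT", "F"),
            ("GGT", "G"), ("CAT", "H"), ("ATT", "I"), ("AAA", "K"), ("CTT", "L"),
            ("ATG", "M"), ("AAT", "N"), ("CCT", "P"), ("CAA", "Q"), ("CGT", "R"),
            ("TCT", "S"), ("ACT", "T"), ("GTT", "V"), ("TGG", "W"), ("TAT", "Y"),
        ]}
        protein = "M" + tail
        cds = "".join(codon[aa] for aa in protein) + "TAA"
        orf = find_orf(dna(cds))
        assert orf.protein.seq == protein


class TestTranslate:
    def test_standard_code(self):
        assert translate(dna("ATGGGT")).seq == "MG"

    def test_ambiguous_codon_is_x(self):
        assert translate(dna("ATGNNN")).seq == "MX"

    def test_internal_stop_errors_with_codon_index(self):
        with pytest.raises(ValueError, match="codon 2"):
            translate(dna("ATGTAAGGG"))

    def test_non_triplet_errors(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            translate(dna("ATGG"))


class TestMolecularWeight:
    def test_glycine_oracle(self):
        # residue mass + one water, from the documented mass table
        assert molecular_weight(prot("G")) == pytest.approx(0.0750672, abs=1e-6)

    def test_two_glycines(self):
        assert molecular_weight(prot("GG")) == pytest.approx(0.1321191, abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet=AA20, min_size=1, max_size=30),
           st.text(alphabet=AA20, min_size=1, max_size=30))
    def test_additivity(self, s1, s2):
        """MW(s1+s2) = MW(s1) + MW(s2) - one water (peptide-bond condensation)."""
        lhs = molecular_weight(prot(s1 + s2))
        rhs = molecular_weight(prot(s1)) + molecular_weight(prot(s2)) - WATER_MASS_DA / 1000
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_matches_biopython_convention(self):
        """Cross-check the mass table against an independent implementation."""
        from Bio.SeqUtils import molecular_weight as bio_mw
        seq = "MKWVTFISLLFLFSSAYS"
        ours = molecular_weight(prot(seq)) * 1000
        theirs = bio_mw(seq, seq_type="protein", monoisotopic=False)
        assert ours == pytest.approx(theirs, rel=5e-4)

    def test_ambiguous_residue_errors(self):
        rec = SeqRecord.__new__(SeqRecord)  # bypass alphabet check deliberately
        object.__setattr__(rec, "id", "x")
        object.__setattr__(rec, "seq", "MB")
        object.__setattr__(rec, "moltype", "protein")
        object.__setattr__(rec, "description", "")
        with pytest.raises(ValueError, match="no mass"):
            molecular_weight(rec)


class TestMotifScan:
    def test_alternative_and_anchor(self):
        hits = scan_motif(prot("QACRG"), "QAC[RG]G", anchor_index=2)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.anchor_pos, h.matched) == (1, 5, 3, "QACRG")

    def test_wildcard_walker_a(self):
        hits = scan_motif(prot("AAGCCGAGKAA"), "GXXGXGK")
        assert len(hits) == 1
        assert hits[0].start == 3 and hits[0].anchor_pos == 3

    def test_no_hits(self):
        assert scan_motif(prot("AAAA"), "GXXGXGK") == []

    def test_non_overlapping_leftmost(self):
        hits = scan_motif(prot("QACGGQACRG"), "QAC[RG]G")
        assert [h.start for h in hits] == [1, 6]

    def test_matched_equals_slice(self):
        seq = prot("LLQACGGLL")
        (h,) = scan_motif(seq, "QAC[RG]G")
        assert h.matched == seq.seq[h.start - 1 : h.end]

    def test_malformed_pattern_errors(self):
        with pytest.raises(ValueError):
            scan_motif(prot("AAAA"), "QAC[RG")


class TestAlignPair:
    def test_self_alignment_blosum62(self):
        aln = align_pair(prot("AAA", "x"), prot("AAA", "y"))
        assert aln.score == 12.0  # 3 x BLOSUM62 A/A
        assert percent_identity(aln) == 100.0

    def test_degapped_strings_equal_inputs(self):
        aln = align_pair(prot("MKVLW", "x"), prot("MKW", "y"))
        assert aln.aligned_query.replace("-", "") == "MKVLW"
        assert aln.aligned_subject.replace("-", "") == "MKW"

    def test_column_map_consistent_with_gaps(self):
        aln = align_pair(prot("MKVLW", "x"), prot("MKW", "y"))
        for (qpos, spos), cq, cs in zip(aln.column_map, aln.aligned_query,
                                        aln.aligned_subject):
            assert (qpos is None) == (cq == "-")
            assert (spos is None) == (cs == "-")

    def test_empty_sequence_errors(self):
        with pytest.raises(Exception):
            align_pair(prot("MK"), SeqRecord(id="e", seq="", moltype="protein"))

    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_score_matches_bruteforce_enumeration(self, mode):
        """DP optimum equals exhaustive enumeration over all alignments
        for short sequences over a 4-letter alphabet."""
        rng = random.Random(7)
        for _ in range(40):
            sa = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            sb = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            dp = align_pair(prot(sa, "a"), prot(sb, "b"), mode=mode).score
            bf = brute_force_score(sa, sb, mode=mode)
            assert dp == pytest.approx(bf), (sa, sb, mode)

    def test_score_symmetric(self):
        a, b = prot("MKVLWAAG", "a"), prot("MKWAG", "b")
        s_ab = align_pair(a, b).score
        s_ba = align_pair(b, a).score
        assert s_ab == s_ba

    def test_identity_symmetric(self):
        a, b = prot("MKVLWAAG", "a"), prot("MKWAG", "b")
        assert percent_identity(align_pair(a, b)) == \
            pytest.approx(percent_identity(align_pair(b, a)))


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(align_pair(prot("MKVL", "a"), prot("MKVL", "b"))) == 100.0

    def test_three_quarters(self):
        aln = align_pair(prot("AAAA", "a"), prot("AAAT", "b"))
        assert percent_identity(aln, "aligned_columns") == 75.0

    def test_denominators_differ_under_gaps(self):
        aln = align_pair(prot("MKVLW", "a"), prot("MKW", "b"))
        ac = percent_identity(aln, "aligned_columns")
        al = percent_identity(aln, "alignment_length")
        sh = percent_identity(aln, "shorter_seq")
        assert al <= ac and sh >= al

    def test_unknown_denominator_errors(self):
        aln = align_pair(prot("MK", "a"), prot("MK", "b"))
        with pytest.raises(ValueError):
            percent_identity(aln, "bogus")
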