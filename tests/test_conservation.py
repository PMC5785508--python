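"""Position mapping through alignments and the conservation reversal."""

import pytest

from ifacecons.conservation import (DELETED, DomainSpan, domain_identity,
                                    interface_identity, map_positions,
                                    reversal_report)
from ifacecons.io_formats import SeqRecord
from ifacecons.seqtools import PairwiseAlignment, align_pair
from ifacecons.synthetic import make_family, regime_spec, FamilySpec


def prot(seq, id="p"):
    return SeqRecord(id=id, seq=seq, moltype="protein")


def manual_alignment(qa, sa, query_id="q", subject_id="s"):
    """Build a PairwiseAlignment from explicit gapped strings."""
    column_map = []
    qi = si = 0
    for cq, cs in zip(qa, sa):
        qpos = spos = None
        if cq != "-":
            qi += 1
            qpos = qi
        if cs != "-":
            si += 1
            spos = si
        column_map.append((qpos, spos))
    return PairwiseAlignment(query_id=query_id, subject_id=subject_id,
                             aligned_query=qa, aligned_subject=sa,
                             score=0.0, mode="global", column_map=column_map)


class TestMapPositions:
    def test_identity_alignment_maps_to_self(self):
        aln = manual_alignment("MKVL", "MKVL")
        assert map_positions(aln, [1, 2, 3, 4]) == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_gapped_positions_flagged_deleted(self):
        # query ABCD vs subject AD: B and C align to gaps
        aln = manual_alignment("ABCD", "A--D")
        assert map_positions(aln, [2, 3]) == {2: DELETED, 3: DELETED}

    def test_order_preserved_on_survivors(self):
        aln = manual_alignment("ABCDE", "A-C-E")
        m = map_positions(aln, [1, 3, 5])
        assert list(m.values()) == [1, 2, 3]

    def test_out_of_span_position_errors(self):
        aln = manual_alignment("MK", "MK")
        with pytest.raises(ValueError, match="outside"):
            map_positions(aln, [5])

    def test_planted_deletion_all_flagged(self):
        """A 10-residue deletion over the interface maps every interface
        position to DELETED."""
        spec = FamilySpec(ref_length=200, domain_span=(41, 160),
                          interface_positions=tuple(range(96, 106)),
                          rate_interface=0.0, rate_background=0.0,
                          deletion_blocks=((96, 10),), n_species=1, seed=4)
        ref, (ortho,), _ = make_family(spec)
        aln = align_pair(ref, ortho, mode="global")
        m = map_positions(aln, spec.interface_positions)
        assert all(v == DELETED for v in m.values())


class TestIdentities:
    def test_self_is_100(self):
        ref = prot("MKVLWAAGMKVLWAAG", "ref")
        aln = align_pair(ref, ref)
        assert interface_identity(ref, ref, [2, 5, 9], aln) == 100.0
        assert domain_identity(ref, ref, DomainSpan("ref", 1, 16), aln) == 100.0

    def test_half_mismatched_interface(self):
        ref = prot("AAAAAAAAAA", "ref")
        ortho = prot("AAAACAAAAC", "o")  # differs at 5 and 10
        aln = manual_alignment(ref.seq, ortho.seq)
        assert interface_identity(ref, ortho, [4, 5, 9, 10], aln) == 50.0

    def test_deleted_policy_mismatch_vs_exclude(self):
        ref = prot("ABCDEFGH".replace("B", "W"), "ref")  # AWCDEFGH
        aln = manual_alignment("AWCDEFGH", "A---EFGH")
        ortho = prot("AEFGH", "o")
        as_mismatch = interface_identity(ref, ortho, [1, 2, 3], aln,
                                         deleted_policy="count_as_mismatch")
        excluded = interface_identity(ref, ortho, [1, 2, 3], aln,
                                      deleted_policy="exclude")
        assert as_mismatch == pytest.approx(100 / 3)
        assert excluded == 100.0

    def test_domain_fully_deleted_scores_zero(self):
        aln = manual_alignment("AAAWWWWAAA", "AAA----AAA")
        ref = prot("AAAWWWWAAA", "ref")
        ortho = prot("AAAAAA", "o")
        assert domain_identity(ref, ortho, DomainSpan("ref", 4, 7), aln) == 0.0

    def test_empty_interface_errors(self):
        ref = prot("MKVL", "ref")
        aln = align_pair(ref, ref)
        with pytest.raises(ValueError):
            interface_identity(ref, ref, [], aln)

    def test_nonuniform_conservation_separates_spans(self):
        """Domain-restricted identity differs from whole-length identity
        when divergence is concentrated outside the domain."""
        spec = FamilySpec(ref_length=300, domain_span=(101, 200),
                          interface_positions=(150,),
                          rate_interface=0.0, rate_background=0.0, seed=9)
        ref, (ortho0,), _ = make_family(spec)
        # mutate the first 50 positions only
        mutated = "".join(
            ("W" if ref.seq[i] != "W" else "Y") if i < 50 else ref.seq[i]
            for i in range(300))
        ortho = prot(mutated, "o")
        aln = align_pair(ref, ortho, mode="global")
        inside = domain_identity(ref, ortho, DomainSpan("ref", 101, 200), aln)
        whole = domain_identity(ref, ortho, DomainSpan("ref", 1, 300), aln)
        assert inside == 100.0
        assert whole < 100.0


class TestReversalReport:
    def test_reference_as_ortholog(self):
        spec = FamilySpec(ref_length=120, domain_span=(11, 110),
                          interface_positions=(20, 40, 60),
                          rate_interface=0.0, rate_background=0.0, seed=1)
        ref, _, _ = make_family(spec)
        clone = SeqRecord(id="clone", seq=ref.seq, moltype="protein")
        rep = reversal_report(ref, [clone], spec.span, spec.interface_positions)
        (row,) = rep.per_species
        assert row["domain_identity"] == 100.0
        assert row["interface_identity"] == 100.0
        assert row["reversal"] is False

    def test_duplicate_species_ids_error(self):
        ref = prot("MKVLWAAGMKVL", "ref")
        o = prot("MKVLWAAGMKVL", "dup")
        with pytest.raises(ValueError, match="duplicated"):
            reversal_report(ref, [o, o], DomainSpan("ref", 1, 12), [2, 5])

    def test_interface_outside_span_errors(self):
        ref = prot("MKVLWAAGMKVL", "ref")
        o = prot("MKVLWAAGMKVL", "o")
        with pytest.raises(ValueError, match="outside"):
            reversal_report(ref, [o], DomainSpan("ref", 1, 6), [10])

    @pytest.mark.parametrize("regime,expected", [("vertebrate", False),
                                                 ("starfish", True)])
    def test_regimes_classified(self, regime, expected):
        """Vertebrate-like families keep the interface above the domain;
        starfish-like families reverse it (20 replicates each)."""
        for seed in range(20):
            spec = regime_spec(regime, seed=seed)
            ref, orthologs, _ = make_family(spec)
            rep = reversal_report(ref, orthologs, spec.span,
                                  spec.interface_positions)
            assert rep.per_species[0]["reversal"] is expected, (regime, seed)

    def test_rows_keep_input_order_and_relabeling_invariance(self):
        spec = regime_spec("vertebrate", seed=5, n_species=3)
        ref, orthologs, _ = make_family(spec)
        rep1 = reversal_report(ref, orthologs, spec.span, spec.interface_positions)
        renamed = [SeqRecord(id=f"z{i}", seq=o.seq, moltype="protein")
                   for i, o in enumerate(orthologs)]
        rep2 = reversal_report(ref, renamed, spec.span, spec.interface_positions)
        assert [r["species_id"] for r in rep1.per_species] == ["sp1", "sp2", "sp3"]
        for a, b in zip(rep1.per_species, rep2.per_species):
            assert a["domain_identity"] == b["domain_identity"]
            assert a["interface_identity"] == b["interface_identity"]
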