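"""Consensus motif scanning, site diffing, and post-edit window evaluation."""

import numpy as np
import pytest

from concestor.motifs import (
    Motif,
    MotifError,
    MotifSite,
    diff_sites,
    evaluate_site_after_edit,
    overlap_events_sites,
    scan_motif,
)
from concestor.mutations import MutationEvent
from concestor.seq_io import CoordinateMap, GappedAlignment, SequenceRecord

from .oracles import COMPLEMENT, naive_motif_scan

ABDB = Motif("ABD-B", "TTTAY")
DSX = Motif("DSX", "RNNACWAWGTNNY")


def ungapped_map(seq: SequenceRecord) -> CoordinateMap:
    return CoordinateMap.from_row(seq.id, seq.residues)


class TestScanMotif:
    def test_forward_match(self):
        sites = scan_motif(SequenceRecord("s", "GTTTATG"), ABDB, strands="forward")
        assert [(s.start, s.end, s.strand, s.matched) for s in sites] == [
            (1, 6, "+", "TTTAT")
        ]

    def test_minus_strand_mapped_to_forward_coordinates(self):
        sites = scan_motif(SequenceRecord("s", "CATAAA"), ABDB, strands="both")
        assert [(s.start, s.end, s.strand) for s in sites] == [(1, 6, "-")]
        assert sites[0].matched == "ATAAA"  # forward-strand slice

    def test_dsx_consensus_match(self):
        sites = scan_motif(SequenceRecord("s", "AGGACAAAGTGGC"), DSX, strands="forward")
        assert [(s.start, s.end) for s in sites] == [(0, 13)]

    def test_invalid_iupac_rejected(self):
        with pytest.raises(MotifError):
            Motif("bad", "TTTAZ")

    def test_overlapping_matches_reported(self):
        sites = scan_motif(SequenceRecord("s", "TTTTATTTAT"), ABDB, strands="forward")
        assert [(s.start, s.end) for s in sites] == [(1, 6), (5, 10)]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        codes = list("ACGTRYSWKMBDHVN")
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 120))))
            motif = Motif("m", "".join(rng.choice(codes, size=int(rng.integers(2, 10)))))
            got = {
                (s.start, s.end, s.strand)
                for s in scan_motif(SequenceRecord("s", seq), motif, strands="both")
            }
            assert got == set(naive_motif_scan(seq, motif.consensus))

    def test_reverse_complement_closure(self):
        """Scanning the reverse complement mirrors coordinates and swaps strands."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            rc = "".join(COMPLEMENT[c] for c in reversed(seq))
            fwd = scan_motif(SequenceRecord("s", seq), DSX, strands="both")
            rev = scan_motif(SequenceRecord("s", rc), DSX, strands="both")
            mirrored = {
                (60 - s.end, 60 - s.start, "-" if s.strand == "+" else "+")
                for s in rev
            }
            assert {(s.start, s.end, s.strand) for s in fwd} == mirrored


class TestDiffSites:
    def make_aln(self, ancestor, allele):
        # the ancestor row rides along so no column is all-gap
        return GappedAlignment([("allele", allele), ("anc", ancestor)]), ancestor

    def test_identical_allele_all_conserved(self):
        aln, anc = self.make_aln("GTTTATGAC", "GTTTATGAC")
        diffs = diff_sites(anc, aln, "allele", [ABDB])
        assert {d.status for d in diffs} == {"conserved"}

    def test_substitution_inside_site_is_lost(self):
        aln, anc = self.make_aln("GTTTACGGG", "GTTGACGGG")
        diffs = diff_sites(anc, aln, "allele", [ABDB])
        lost = [d for d in diffs if d.status == "lost"]
        assert len(lost) == 1
        assert lost[0].site.interval == (1, 6)

    def test_allele_only_match_is_gained(self):
        aln, anc = self.make_aln("GTCTATGGG", "GTTTATGGG")
        diffs = diff_sites(anc, aln, "allele", [ABDB])
        gained = [d for d in diffs if d.status == "gained"]
        assert len(gained) == 1
        assert gained[0].site.interval == (1, 6)

    def test_deletion_over_site_is_lost(self):
        aln, anc = self.make_aln("GTTTATGCC", "GT--ATGCC")
        diffs = diff_sites(anc, aln, "allele", [ABDB])
        assert [d.status for d in diffs if d.site.interval == (1, 6)] == ["lost"]

    def test_self_diff_of_study_scale_consensus(self, study_ds, study_recon):
        """Diffing an allele against itself yields conserved sites only."""
        aln = GappedAlignment(
            [("self", study_recon.consensus), *study_ds.alignment]
        )
        diffs = diff_sites(study_recon.consensus, aln, "self")
        assert {d.status for d in diffs} == {"conserved"}


class TestOverlapEventsSites:
    def test_one_bp_overlap_geometry(self):
        """A 9-bp deletion ending one base into a downstream site overlaps 1 bp."""
        seq = SequenceRecord("s", "A" * 40)
        ev = MutationEvent("deletion", 10, 19, "A" * 9, "")
        site = MotifSite("s", 18, 31, "+", "A" * 13, "DSX")
        records = overlap_events_sites([ev], [site], ungapped_map(seq))
        assert len(records) == 1 and records[0].overlap_bp == 1

    def test_disjoint_intervals_no_record(self):
        seq = SequenceRecord("s", "A" * 40)
        ev = MutationEvent("substitution", 5, 6, "A", "C")
        site = MotifSite("s", 18, 31, "+", "A" * 13, "DSX")
        assert overlap_events_sites([ev], [site], ungapped_map(seq)) == []

    def test_nested_event_overlap_equals_event_length(self):
        seq = SequenceRecord("s", "A" * 40)
        ev = MutationEvent("deletion", 20, 25, "A" * 5, "")
        site = MotifSite("s", 18, 31, "+", "A" * 13, "DSX")
        records = overlap_events_sites([ev], [site], ungapped_map(seq))
        assert records[0].overlap_bp == 5


class TestEvaluateSiteAfterEdit:
    def build_e_mutation_case(self):
        # 40-bp sequence with a DSX site at [18, 31) and a 9-bp deletion at
        # [10, 19) whose last base is the site's first; the base at position
        # 9 ('G') satisfies the consensus R, so the shifted window still binds.
        site_seq = "AGGACAAAGTGGC"
        seq = "AAAAAAAAA" + "G" + "AAAAAAAA" + site_seq + "AAAAAAAAA"
        record = SequenceRecord("s", seq)
        event = MutationEvent("deletion", 10, 19, seq[10:19], "")
        site = MotifSite("s", 18, 31, "+", site_seq, "DSX")
        return record, event, site

    def test_deletion_one_bp_into_site_can_preserve_consensus(self):
        record, event, site = self.build_e_mutation_case()
        assert evaluate_site_after_edit(record, event, site, DSX, ungapped_map(record))

    def test_substitution_of_invariant_position_breaks_site(self):
        site_seq = "AGGACAAAGTGGC"
        seq = "AAAA" + site_seq + "AAAA"
        record = SequenceRecord("s", seq)
        # position 8 of the site is the invariant G of the consensus
        event = MutationEvent("substitution", 12, 13, "G", "T")
        site = MotifSite("s", 4, 17, "+", site_seq, "DSX")
        assert not evaluate_site_after_edit(record, event, site, DSX, ungapped_map(record))

    def test_event_outside_site_keeps_match_status(self):
        site_seq = "AGGACAAAGTGGC"
        seq = "AAAA" + site_seq + "AAAA"
        record = SequenceRecord("s", seq)
        event = MutationEvent("substitution", 0, 1, "A", "C")
        site = MotifSite("s", 4, 17, "+", site_seq, "DSX")
        assert evaluate_site_after_edit(record, event, site, DSX, ungapped_map(record))

    def test_ancestral_mismatch_raises(self):
        record = SequenceRecord("s", "ACGTACGT")
        event = MutationEvent("substitution", 0, 1, "G", "T")
        site = MotifSite("s", 2, 7, "+", "GTACG", "ABD-B")
        with pytest.raises(ValueError, match="does not match"):
            evaluate_site_after_edit(record, event, site, ABDB, ungapped_map(record))
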