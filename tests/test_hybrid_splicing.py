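"""Donor scanning, hybrid-splice calling, and the distance test."""

import re

import numpy as np
import pytest

from tesplice.hybrid_splicing import (
    call_hybrid_events,
    find_donor_motifs,
    splicing_competence_test,
)
from tesplice.insertion_catalog import TEInsertion, classify_insertion
from tesplice.intervals import Gene, GenomicInterval, TranscriptModel


class TestDonorScan:
    def test_planted_offset(self, l3):
        sites = find_donor_motifs(l3.te_consensus, l3.ltr_end)
        assert len(sites) == 1
        assert sites[0].offset == 43
        assert sites[0].heptamer == "GTAAGTG"

    def test_no_match(self):
        assert find_donor_motifs("AAAAAAAAAA", 0) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        sites = find_donor_motifs(seq, 100, pattern="GTAAGT")
        brute = [
            m.start() - 100
            for m in re.finditer("(?=GTAAGT)", seq)
            if m.start() >= 100 and m.start() + 7 <= len(seq)
        ]
        assert [s.offset for s in sites] == brute
        assert [s.offset for s in sites] == sorted(s.offset for s in sites)

    def test_iupac_weak_donor_pattern(self):
        seq = "A" * 50 + "GTATGTT" + "A" * 50
        sites = find_donor_motifs(seq, 10, pattern="GTATGTT")
        assert [s.offset for s in sites] == [40]

    def test_non_gt_pattern_rejected(self):
        with pytest.raises(ValueError, match="GT"):
            find_donor_motifs("ACGT", 0, pattern="AGAAGT")


class TestHybridCalling:
    def test_l3_fixture_single_event(self, l3):
        call = classify_insertion(l3.insertion, [l3.gene])
        events, verdicts = call_hybrid_events(
            [l3.insertion], [call],
            [l3.hybrid_transcript, l3.canonical_transcript], [l3.gene],
        )
        assert len(events) == 1
        ev = events[0]
        assert sorted(ev.skipped_exons) == [1, 2, 3]
        assert ev.acceptor_exon_ordinal == 4
        assert ev.donor_offset_on_te == l3.ltr_end + 43
        assert l3.insertion.interval.contains_point(ev.donor_genomic)
        assert verdicts == {"l3_te": True}

    def test_canonical_only_yields_nothing(self, l3):
        call = classify_insertion(l3.insertion, [l3.gene])
        events, verdicts = call_hybrid_events(
            [l3.insertion], [call], [l3.canonical_transcript], [l3.gene]
        )
        assert events == []
        assert verdicts == {"l3_te": False}

    def test_shift_invariance(self, l3):
        """Adding a constant to every coordinate leaves the call unchanged."""
        off = 12345

        def shift_tx(tx):
            return TranscriptModel(
                tx.transcript_id, tx.chrom, tx.strand,
                [(s + off, e + off) for s, e in tx.exons], gene_id=tx.gene_id,
            )

        gene = Gene(l3.gene.gene_id, l3.gene.chrom, l3.gene.strand,
                    [shift_tx(l3.gene.transcripts[0])])
        ins = TEInsertion(
            "l3_te", "Springer", l3.insertion.interval.shift(off),
            cons_span=l3.insertion.cons_span,
        )
        call = classify_insertion(ins, [gene])
        events, _ = call_hybrid_events(
            [ins], [call],
            [shift_tx(l3.hybrid_transcript), shift_tx(l3.canonical_transcript)], [gene],
        )
        assert len(events) == 1
        assert sorted(events[0].skipped_exons) == [1, 2, 3]
        assert events[0].donor_offset_on_te == l3.ltr_end + 43

    def test_reverse_complement_invariance(self, l3):
        """Mirroring the whole locus onto the minus strand preserves the call."""
        L = len(l3.sequence)

        def mirror_exons(exons):
            return sorted((L - e, L - s) for s, e in exons)

        gene = Gene(
            "g_rc", l3.gene.chrom, "-",
            [TranscriptModel("t_rc", l3.gene.chrom, "-",
                             mirror_exons(l3.gene.transcripts[0].exons), gene_id="g_rc")],
        )
        iv = l3.insertion.interval
        ins = TEInsertion(
            "te_rc", "Springer", GenomicInterval(iv.chrom, L - iv.end, L - iv.start, "-"),
            cons_span=l3.insertion.cons_span,
        )
        hybrid = TranscriptModel(
            "h_rc", l3.gene.chrom, "-", mirror_exons(l3.hybrid_transcript.exons)
        )
        canonical = TranscriptModel(
            "c_rc", l3.gene.chrom, "-", mirror_exons(l3.canonical_transcript.exons)
        )
        call = classify_insertion(ins, [gene])
        assert (call.context, call.orientation, call.intron_ordinal) == (
            "intronic", "forward", 3,
        )
        events, _ = call_hybrid_events([ins], [call], [hybrid, canonical], [gene])
        assert len(events) == 1
        assert sorted(events[0].skipped_exons) == [1, 2, 3]
        assert events[0].donor_offset_on_te == l3.ltr_end + 43
        assert events[0].te_segment_length == l3.ltr_end + 43 - 100

    def test_unknown_transcript_chromosome(self, l3):
        call = classify_insertion(l3.insertion, [l3.gene])
        alien = TranscriptModel("bad", "chrZ", "+", [(0, 10), (20, 30)])
        with pytest.raises(ValueError, match="chrZ"):
            call_hybrid_events([l3.insertion], [call], [alien], [l3.gene])

    def test_min_support_threshold(self, l3):
        call = classify_insertion(l3.insertion, [l3.gene])
        _, verdicts = call_hybrid_events(
            [l3.insertion], [call], [l3.hybrid_transcript], [l3.gene], min_support=2
        )
        assert verdicts == {"l3_te": False}

    def test_planted_events_on_bundle(self, small_bundle):
        """Every planted hybrid transcript and no canonical one yields an event."""
        from tesplice.insertion_catalog import classify_all

        ds = small_bundle
        truth = {r["insertion_id"]: r for r in ds.truth["insertions"]}
        for hap in ds.config.haplotypes:
            calls = classify_all(ds.insertions[hap], ds.genes[hap])
            events, verdicts = call_hybrid_events(
                ds.insertions[hap], calls, ds.transcripts[hap], ds.genes[hap]
            )
            for iid, v in verdicts.items():
                assert v == truth[iid]["spliced"]
            ins_by = {i.insertion_id: i for i in ds.insertions[hap]}
            gene_by = {g.gene_id: g for g in ds.genes[hap]}
            for ev in events:
                iv = ins_by[ev.insertion_id].interval
                assert iv.contains_point(ev.donor_genomic)
                host = gene_by[truth[ev.insertion_id]["host_gene"]]
                iso = host.reference_isoform()
                acceptor_exon = iso.exons_in_transcription_order()[
                    ev.acceptor_exon_ordinal - 1
                ]
                if host.strand != "-":
                    assert ev.donor_genomic < acceptor_exon[0]
                else:
                    assert ev.donor_genomic > acceptor_exon[1]


class TestCompetence:
    def test_tiny_exact_case(self):
        res = splicing_competence_test([1, 2], [3, 4])
        assert res.u == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.median_with == 1.5
        assert res.median_without == 3.5
        assert res.delta == 2.0

    def test_identical_groups(self):
        res = splicing_competence_test([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0
        assert res.delta == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            splicing_competence_test([], [1.0])
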