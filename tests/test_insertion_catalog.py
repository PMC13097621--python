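"""Insertion context classification, distances, flank lifting, stratification."""

import numpy as np
import pytest

from tesplice.insertion_catalog import (
    ContextCall,
    TEInsertion,
    classify_insertion,
    context_composition,
    distance_to_downstream_exon,
    expression_stratify,
    filter_full_length,
    genome_feature_composition,
    intron_position_distribution,
    lift_by_flanks,
)
from tesplice.intervals import Gene, GenomicInterval, TranscriptModel
from tesplice.io_formats import AlignmentBlock


def _te(start, end, strand="+", chrom="chr1", te_id="te1"):
    return TEInsertion(te_id, "Springer", GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def plus_gene():
    tx = TranscriptModel("t1", "chr1", "+", [(100, 200), (300, 400)], gene_id="g1")
    return Gene("g1", "chr1", "+", [tx])


class TestFullLength:
    def test_springer_thresholds(self):
        near = [_te(0, 7546), _te(0, 7500), _te(0, 7499)]
        kept = filter_full_length(near, consensus_len=7546, min_len=7500)
        assert [t.length for t in kept] == [7546, 7500]
        # fraction bound: 0.995 * 7546 = 7508.27, so 7500 is excluded
        kept = filter_full_length(near, consensus_len=7546, min_frac=0.995)
        assert [t.length for t in kept] == [7546]

    def test_empty_and_errors(self):
        assert filter_full_length([], min_len=10) == []
        with pytest.raises(ValueError):
            filter_full_length([], consensus_len=0, min_frac=0.5)
        with pytest.raises(ValueError):
            filter_full_length([])


class TestClassify:
    def test_intronic_forward(self, plus_gene):
        call = classify_insertion(_te(250, 260, "+"), [plus_gene])
        assert (call.context, call.orientation, call.intron_ordinal) == (
            "intronic", "forward", 1,
        )
        assert call.host_gene == "g1"

    def test_intronic_reverse(self, plus_gene):
        call = classify_insertion(_te(250, 260, "-"), [plus_gene])
        assert (call.context, call.orientation) == ("intronic", "reverse")

    def test_intergenic(self, plus_gene):
        call = classify_insertion(_te(500, 600), [plus_gene])
        assert call.context == "intergenic"
        assert call.host_gene is None
        assert call.orientation == "not-applicable"

    def test_exonic_one_bp_overlap_rule(self, plus_gene):
        call = classify_insertion(_te(190, 210), [plus_gene])
        assert call.context == "exonic"

    def test_unknown_chromosome(self, plus_gene):
        with pytest.raises(ValueError, match="unknown chromosome"):
            classify_insertion(_te(0, 10, chrom="chrX"), [plus_gene])

    def test_minus_strand_ordinal_is_transcription_order(self):
        tx = TranscriptModel(
            "t1", "chr1", "-", [(100, 200), (300, 400), (500, 600)], gene_id="g1"
        )
        gene = Gene("g1", "chr1", "-", [tx])
        # genomic intron (400, 500) is the FIRST intron of a minus gene
        call = classify_insertion(_te(420, 440, "-"), [gene])
        assert call.intron_ordinal == 1
        assert call.orientation == "forward"

    def test_multi_gene_overlap_sets_ambiguity(self, plus_gene):
        other = Gene(
            "g0", "chr1", "-",
            [TranscriptModel("t0", "chr1", "-", [(0, 150), (380, 450)], gene_id="g0")],
        )
        call = classify_insertion(_te(250, 260, "+"), [plus_gene, other])
        assert call.ambiguous
        assert call.context == "intronic"
        # the enclosing intron of g1 (300-200=100) is shorter than g0's (230)
        assert call.host_gene == "g1"


class TestComposition:
    def test_pure_intronic(self):
        calls = [ContextCall(f"i{k}", "intronic", host_gene="g", orientation="forward")
                 for k in range(10)]
        comp = context_composition(calls)
        assert comp == {"exonic": 0.0, "intronic": 1.0, "intergenic": 0.0}

    def test_fractions_sum_to_one(self):
        calls = (
            [ContextCall("a", "exonic", host_gene="g", orientation="forward")] * 17
            + [ContextCall("b", "intronic", host_gene="g", orientation="reverse")] * 200
            + [ContextCall("c", "intergenic")] * 73
        )
        comp = context_composition(calls)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
        assert comp["exonic"] == pytest.approx(17 / 290)

    def test_empty_calls_error(self):
        with pytest.raises(ValueError):
            context_composition([])

    def test_genome_partition(self):
        tx = TranscriptModel("t1", "chr1", "+", [(100, 200), (350, 400)], gene_id="g1")
        gene = Gene("g1", "chr1", "+", [tx])
        comp = genome_feature_composition([gene], 1000)
        assert comp == {"exonic": 0.15, "intronic": 0.15, "intergenic": 0.70}
        assert sum(comp.values()) == pytest.approx(1.0)


class TestDownstreamDistance:
    def test_basic(self, plus_gene):
        assert distance_to_downstream_exon(_te(250, 260), plus_gene) == 40

    def test_abutting_exon(self, plus_gene):
        assert distance_to_downstream_exon(_te(250, 300), plus_gene) == 0

    def test_no_downstream_exon_is_none(self, plus_gene):
        assert distance_to_downstream_exon(_te(450, 460), plus_gene) is None

    def test_mirror_symmetry(self, plus_gene):
        """A reverse-complemented layout gives the identical distance."""
        L = 1000
        mirrored_exons = sorted((L - e, L - s) for s, e in plus_gene.transcripts[0].exons)
        minus_gene = Gene(
            "g1m", "chr1", "-",
            [TranscriptModel("t1m", "chr1", "-", mirrored_exons, gene_id="g1m")],
        )
        d_plus = distance_to_downstream_exon(_te(250, 260), plus_gene)
        d_minus = distance_to_downstream_exon(_te(L - 260, L - 250, "-"), minus_gene)
        assert d_plus == d_minus == 40

    def test_legend_variant_measures_to_exon_end(self, plus_gene):
        assert distance_to_downstream_exon(_te(250, 260), plus_gene, boundary="end") == 140


class TestLiftByFlanks:
    def _hit(self, start, end, chrom="chr2", strand="+"):
        return AlignmentBlock(
            GenomicInterval("flank", 0, end - start),
            GenomicInterval(chrom, start, end),
            strand,
        )

    def test_concordant_midpoint(self):
        site = lift_by_flanks("i1", self._hit(1000, 1100), self._hit(1105, 1205))
        assert site.status == "concordant"
        assert site.target_position == 1102

    def test_discordant_chrom(self):
        site = lift_by_flanks("i1", self._hit(0, 100, chrom="c1"), self._hit(0, 100, chrom="c2"))
        assert site.status == "discordant-chrom"

    def test_discordant_strand(self):
        site = lift_by_flanks("i1", self._hit(0, 100), self._hit(200, 300, strand="-"))
        assert site.status == "discordant-strand"

    def test_discordant_gap(self):
        site = lift_by_flanks("i1", self._hit(1000, 1100), self._hit(6100, 6200), max_gap=100)
        assert site.status == "discordant-gap"

    def test_missing_hit_is_unmapped(self):
        assert lift_by_flanks("i1", None, self._hit(0, 100)).status == "unmapped"

    def test_roundtrip_on_same_assembly(self):
        """Flanks extracted around a point map back to the point +/- 1 nt."""
        point = 54321
        left = self._hit(point - 100, point)
        right = self._hit(point, point + 100)
        site = lift_by_flanks("i1", left, right)
        assert site.status == "concordant"
        assert abs(site.target_position - point) <= 1


class TestStratification:
    def test_intron_histogram(self):
        calls = [
            ContextCall(f"i{k}", "intronic", host_gene="g", orientation="forward",
                        intron_ordinal=1)
            for k in range(5)
        ]
        assert intron_position_distribution(calls) == {1: 5}

    def test_uniform_placement_gives_flat_enrichment(self):
        rng = np.random.default_rng(0)
        genes = {f"g{k}": float(v) for k, v in enumerate(rng.lognormal(1, 1, 500))}
        hosts = rng.choice(list(genes), size=400)
        calls = [
            ContextCall(f"i{k}", "intronic", host_gene=h, orientation="forward")
            for k, h in enumerate(hosts)
        ]
        df = expression_stratify(calls, genes, n_bins=5)
        assert df["n_insertions"].sum() == 400
        assert df["n_genes"].sum() == 500
        # binomial fluctuation at n=400/5 bins: allow wide null band
        assert np.all(np.abs(df["enrichment"] - 1.0) < 0.35)

    def test_expression_weighted_placement_is_monotone(self):
        rng = np.random.default_rng(1)
        expr = np.sort(rng.lognormal(1, 1.5, 500))
        genes = {f"g{k:03d}": float(v) for k, v in enumerate(expr)}
        p = expr / expr.sum()
        hosts = rng.choice(sorted(genes), size=600, p=p)
        calls = [
            ContextCall(f"i{k}", "intronic", host_gene=h, orientation="forward")
            for k, h in enumerate(hosts)
        ]
        df = expression_stratify(calls, genes, n_bins=4)
        e = df["enrichment"].to_numpy()
        assert np.all(np.diff(e) > 0)

    def test_nbins_validation(self):
        with pytest.raises(ValueError):
            expression_stratify([], {"g": 1.0}, n_bins=1)
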