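"""Gene-structure handling: major transcript choice, ambiguity filters,
promoter windows, GTF round trip."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from methmir.annotation import (GeneModel, TranscriptModel,
                                build_gene_models, filter_unambiguous_genes,
                                promoter_interval, read_gtf,
                                select_major_transcript)


def tx(tid, gene="g1", chrom="chr1", strand="+", tss=10_000, span=None,
       cds=900, utr3=(12_000, 12_500)):
    span = span or (tss, tss + 3000)
    return TranscriptModel(transcript_id=tid, gene_id=gene, chrom=chrom,
                           strand=strand, tss=tss, tx_interval=span,
                           cds_length=cds, utr3_interval=utr3)


class TestMajorTranscript:
    def test_single_transcript_is_identity(self):
        t = tx("t1")
        assert select_major_transcript([t]) is t

    def test_longest_cds_wins(self):
        a, b = tx("t1", cds=900), tx("t2", cds=300)
        assert select_major_transcript([a, b]) is a
        assert select_major_transcript([b, a]) is a

    def test_tie_broken_by_span_then_id(self):
        long_span = tx("t2", cds=500, span=(10_000, 12_000))
        short_span = tx("t1", cds=500, span=(10_000, 11_500))
        assert select_major_transcript([short_span, long_span]) is long_span
        same_a = tx("tb", cds=500, span=(10_000, 12_000))
        same_b = tx("ta", cds=500, span=(10_000, 12_000))
        assert select_major_transcript([same_a, same_b]) is same_b

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no transcripts"):
            select_major_transcript([])

    @given(st.permutations(range(6)))
    def test_order_invariance(self, perm):
        txs = [tx(f"t{i}", cds=300 * (i % 3), span=(10_000, 10_500 + 100 * i))
               for i in range(6)]
        shuffled = [txs[i] for i in perm]
        assert select_major_transcript(shuffled).transcript_id == \
            select_major_transcript(txs).transcript_id


class TestPromoterInterval:
    @pytest.mark.parametrize("tss,strand,expected,clipped", [
        (10_000, "+", (9_000, 10_200), False),
        (10_000, "-", (9_800, 11_000), False),
        (500, "+", (0, 700), True),
    ])
    def test_window_placement(self, tss, strand, expected, clipped):
        s, e, c = promoter_interval(tss, strand)
        assert (s, e) == expected
        assert c is clipped

    @given(st.integers(min_value=1000, max_value=10**8),
           st.sampled_from("+-"))
    def test_unclipped_length_is_window_sum(self, tss, strand):
        s, e, c = promoter_interval(tss, strand)
        assert not c
        assert e - s == 1200


class TestAmbiguityFilter:
    def test_close_alternative_tss_retained(self):
        txs = [tx("t1", cds=900, tss=10_000),
               tx("t2", cds=300, tss=10_150)]
        assert len(build_gene_models(txs)) == 1

    def test_distant_alternative_tss_excluded(self):
        # the retention boundary is strictly more than 200 bp away
        keep = [tx("t1", cds=900, tss=10_000), tx("t2", cds=300, tss=10_200)]
        drop = [tx("t1", cds=900, tss=10_000), tx("t2", cds=300, tss=10_201)]
        assert len(build_gene_models(keep)) == 1
        assert len(build_gene_models(drop)) == 0

    def test_disjoint_utrs_excluded(self):
        txs = [tx("t1", cds=900, utr3=(12_000, 12_500)),
               tx("t2", cds=300, utr3=(13_000, 13_400))]
        assert build_gene_models(txs) == []

    def test_filter_is_subset_and_idempotent(self):
        genes = [
            GeneModel("g1", "chr1", "+", 10_000, (9_000, 10_200),
                      (12_000, 12_500), alt_tss=[10_000, 10_100]),
            GeneModel("g2", "chr1", "+", 20_000, (19_000, 20_200),
                      (22_000, 22_500), alt_tss=[20_000, 20_500]),
        ]
        once = filter_unambiguous_genes(genes)
        assert [g.gene_id for g in once] == ["g1"]
        assert filter_unambiguous_genes(once) == once


class TestGtfRoundTrip:
    def test_read_gtf_converts_coordinates(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(
            'chr1\tsim\ttranscript\t501\t4000\t.\t+\t.\t'
            'gene_id "gA"; transcript_id "gA.t1";\n'
            'chr1\tsim\tCDS\t701\t1600\t.\t+\t.\t'
            'gene_id "gA"; transcript_id "gA.t1";\n'
            'chr1\tsim\tthree_prime_utr\t2101\t4000\t.\t+\t.\t'
            'gene_id "gA"; transcript_id "gA.t1";\n')
        (t,) = read_gtf(gtf)
        assert t.tss == 500
        assert t.tx_interval == (500, 4000)
        assert t.cds_length == 900
        assert t.utr3_interval == (2100, 4000)
        (g,) = build_gene_models([t])
        assert g.promoter_interval == (0, 700)
        assert g.clipped
        assert g.utr3_length == 1900

    def test_minus_strand_tss_is_transcript_end(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(
            'chr2\tsim\ttranscript\t5001\t8000\t.\t-\t.\t'
            'gene_id "gB"; transcript_id "gB.t1";\n'
            'chr2\tsim\tthree_prime_utr\t5001\t5400\t.\t-\t.\t'
            'gene_id "gB"; transcript_id "gB.t1";\n')
        (t,) = read_gtf(gtf)
        assert t.tss == 7999

    def test_synthetic_annotation_filters(self, small_bundle):
        transcripts = read_gtf(small_bundle.paths["gtf"])
        genes = build_gene_models(transcripts)
        truth = small_bundle.truth
        expected = set(truth.loc[truth["retained_expected"], "gene_id"])
        assert {g.gene_id for g in genes} == expected
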