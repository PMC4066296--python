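"""Covariates, functional categories and regulatory-sequence classes."""
import math

import numpy as np
import pytest

from regprio.annotate import (
    NO_TSS_DISTANCE,
    GeneModel,
    Variant,
    annotate_covariates,
    assign_functional_category,
    classify_regulatory_sequences,
    gc_content,
    nearest_tss_distance,
)
from regprio.intervals import FeatureTrack, GenomicInterval, merge_intervals


def var(pos, chrom="chr1", vid="v1", major="A", minor="G"):
    return Variant(id=vid, chrom=chrom, pos=pos, major=major, minor=minor, maf=0.2)


def plus_gene(gene_id="g1", chrom="chr1", start=1000, end=2000):
    exon = GenomicInterval(chrom, start, end, strand="+")
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand="+", tss=start, tts=end - 1, exons=[exon]
    )


class TestVariantValidation:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            Variant(id="x", chrom="chr1", pos=1, major="A", minor="A", maf=0.2)

    @pytest.mark.parametrize("maf", [0.0, 0.6, -0.1])
    def test_maf_bounds(self, maf):
        with pytest.raises(ValueError):
            Variant(id="x", chrom="chr1", pos=1, major="A", minor="G", maf=maf)


class TestGcContent:
    def test_all_gc_window(self):
        assert gc_content({"chr1": "G" * 101}, "chr1", 50, flank=50) == 1.0

    def test_at_window(self):
        assert gc_content({"chr1": "AT" * 60}, "chr1", 50, flank=50) == 0.0

    def test_manual_count_with_ns(self):
        # window of 7 around pos 3: ACGTNNC -> 3 GC among 5 non-N
        genome = {"chr1": "ACGTNNC"}
        assert gc_content(genome, "chr1", 3, flank=3) == pytest.approx(3 / 5)

    def test_all_n_window_is_nan(self):
        assert math.isnan(gc_content({"chr1": "N" * 50}, "chr1", 25, flank=10))

    def test_window_clipped_at_chromosome_start(self):
        assert gc_content({"chr1": "GGGGAAAA"}, "chr1", 1, flank=3) == pytest.approx(4 / 5)


class TestNearestTss:
    def test_snp_at_tss(self):
        assert nearest_tss_distance(var(1000), [plus_gene()]) == 0

    def test_between_two_tss(self):
        genes = [plus_gene("a", start=100, end=220), plus_gene("b", start=300, end=400)]
        assert nearest_tss_distance(var(150), genes) == 50

    def test_empty_gene_set_errors(self):
        with pytest.raises(ValueError):
            nearest_tss_distance(var(5), [])

    def test_geneless_chromosome_gets_sentinel(self):
        assert nearest_tss_distance(var(5, chrom="chr2"), [plus_gene()]) == NO_TSS_DISTANCE

    def test_random_agrees_with_brute_force(self, rng):
        genes = [plus_gene(f"g{i}", start=int(s), end=int(s) + 500)
                 for i, s in enumerate(rng.integers(0, 100_000, 30))]
        for pos in rng.integers(0, 100_000, 100):
            v = var(int(pos))
            brute = min(abs(int(pos) - g.tss) for g in genes)
            assert nearest_tss_distance(v, genes) == brute

    def test_annotate_covariates_matches_single_snp_functions(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        genome = {"chr1": seq}
        genes = [plus_gene("g", start=5000, end=6000)]
        variants = [var(int(p), vid=f"v{i}") for i, p in enumerate(rng.integers(0, 20_000, 50))]
        annotate_covariates(variants, genome, genes)
        for v in variants:
            assert v.gc500 == pytest.approx(gc_content(genome, "chr1", v.pos))
            assert v.tss_dist == nearest_tss_distance(v, genes)


class TestFunctionalCategory:
    def test_utr5_beats_intron_of_other_gene(self):
        # gene A: 5'UTR at [1000,1100); gene B: intron-containing body overlapping it
        exon_a = GenomicInterval("chr1", 1000, 1200, strand="+")
        gene_a = GeneModel(
            "a", "chr1", "+", tss=1000, tts=1199, exons=[exon_a],
            utr5=[GenomicInterval("chr1", 1000, 1100, strand="+")],
        )
        gene_b = GeneModel(
            "b", "chr1", "+", tss=500, tts=2999,
            exons=[GenomicInterval("chr1", 500, 600, strand="+"),
                   GenomicInterval("chr1", 2900, 3000, strand="+")],
        )
        assert assign_functional_category(var(1050), [gene_a, gene_b]) == "5UTR"

    def test_far_from_any_gene_is_intergenic(self):
        assert assign_functional_category(var(50_000), [plus_gene()]) == "intergenic"

    def test_minus_strand_downstream_is_genomic_left(self):
        # minus-strand gene spanning [10000, 20000): TSS at 19999, TTS at 10000
        exon = GenomicInterval("chr1", 10_000, 20_000, strand="-")
        g = GeneModel("g", "chr1", "-", tss=19_999, tts=10_000, exons=[exon])
        assert assign_functional_category(var(5_000), [g]) == "downstream"
        assert assign_functional_category(var(25_000), [g]) == "upstream"

    def test_intron_is_genic(self):
        g = GeneModel(
            "g", "chr1", "+", tss=1000, tts=4999,
            exons=[GenomicInterval("chr1", 1000, 1200, strand="+"),
                   GenomicInterval("chr1", 4800, 5000, strand="+")],
        )
        assert assign_functional_category(var(3000), [g]) == "genic"
        assert assign_functional_category(var(1100), [g]) == "exon"


class TestRegulatoryClasses:
    def test_worked_example(self):
        dnase = FeatureTrack("d", [GenomicInterval("chr1", 0, 100)])
        h3k4 = FeatureTrack("h", [GenomicInterval("chr1", 40, 60)])
        classes, missing = classify_regulatory_sequences(
            dnase=dnase, h3k4me3=h3k4, exons=[GenomicInterval("chr1", 80, 90)]
        )
        assert [(iv.start, iv.end) for iv in classes["pEnh"]] == [(0, 40), (60, 80), (90, 100)]
        assert missing == ["insulator"]

    def test_no_h3k4me3_no_exons_penh_is_dnase(self):
        dnase = FeatureTrack("d", [GenomicInterval("chr1", 10, 50)])
        classes, _ = classify_regulatory_sequences(dnase=dnase)
        assert [(iv.start, iv.end) for iv in classes["pEnh"]] == [(10, 50)]

    def test_dnase_within_h3k4me3_gives_empty_penh(self):
        dnase = FeatureTrack("d", [GenomicInterval("chr1", 10, 50)])
        h3k4 = FeatureTrack("h", [GenomicInterval("chr1", 0, 100)])
        classes, _ = classify_regulatory_sequences(dnase=dnase, h3k4me3=h3k4)
        assert classes["pEnh"] == []

    def test_missing_dnase_flags_dependent_classes(self):
        classes, missing = classify_regulatory_sequences(
            h3k4me3=FeatureTrack("h", [GenomicInterval("chr1", 0, 10)])
        )
        assert "open_chromatin" in missing and "pEnh" in missing
        assert "promoter" in classes

    def test_penh_disjoint_from_promoter_and_inside_open(self, rng):
        def random_ivs(n):
            return [
                GenomicInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 9000, n), rng.integers(50, 500, n))
            ]

        def cover(ivs, n=10_000):
            mask = np.zeros(n, dtype=bool)
            for iv in merge_intervals(ivs):
                mask[iv.start : iv.end] = True
            return mask

        for _ in range(5):
            dnase = FeatureTrack("d", random_ivs(30))
            h3k4 = FeatureTrack("h", random_ivs(20))
            classes, _ = classify_regulatory_sequences(
                dnase=dnase, h3k4me3=h3k4, exons=random_ivs(10)
            )
            penh = cover(classes["pEnh"])
            assert not np.any(penh & cover(classes["promoter"]))
            assert np.all(~penh | cover(classes["open_chromatin"]))
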