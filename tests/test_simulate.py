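"""Determinism and statistical structure of the synthetic generator."""
import numpy as np
import pytest

from regprio.pwm import allelic_best_scores, build_pwm
from regprio.rpi import nearby_differential_expression
from regprio.simulate import (
    SimulationConfig,
    default_planted_pfm,
    generate_dataset,
    generate_expression,
    generate_genome,
    generate_hic,
    generate_snp_pool,
    make_tads,
    plant_motif_snps,
    write_dataset,
)

SMALL = dict(
    chrom_sizes={"chr1": 300_000},
    n_genes=15,
    n_pool_snps=400,
    n_fg_snps=40,
    n_samples=40,
    ld_partner_pairs=5,
    n_hic_pairs=2000,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        b1 = generate_dataset(SimulationConfig(seed=42, **SMALL))
        b2 = generate_dataset(SimulationConfig(seed=42, **SMALL))
        assert b1.genome == b2.genome
        assert [(v.id, v.pos, v.major, v.minor, v.maf) for v in b1.fg] == [
            (v.id, v.pos, v.major, v.minor, v.maf) for v in b2.fg
        ]
        assert np.array_equal(b1.genotypes.dosages, b2.genotypes.dosages)
        assert b1.expression.equals(b2.expression)
        assert b1.hic_pairs == b2.hic_pairs
        for cond in b1.tracks:
            for assay in b1.tracks[cond]:
                for r1, r2 in zip(b1.tracks[cond][assay], b2.tracks[cond][assay]):
                    assert r1.intervals == r2.intervals

    def test_different_seed_differs(self):
        b1 = generate_dataset(SimulationConfig(seed=1, **SMALL))
        b2 = generate_dataset(SimulationConfig(seed=2, **SMALL))
        assert b1.genome != b2.genome


class TestGenome:
    def test_gc_parameter_realized_within_one_percent(self):
        cfg = SimulationConfig(seed=3, chrom_sizes={"chr1": 1_000_000}, gc=0.6)
        genome, _ = generate_genome(cfg, 3)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.01

    def test_requested_gene_count_emitted(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        _, genes = generate_genome(cfg, 4)
        assert len(genes) == cfg.n_genes

    def test_tiny_chromosome_rejected(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 5000})
        with pytest.raises(ValueError, match="10 kb"):
            generate_genome(cfg, 0)


class TestPool:
    def test_maf_bounds_and_reference_majors(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        genome, genes = generate_genome(cfg, 5)
        pool, _, _ = generate_snp_pool(cfg, genome, genes, 5)
        assert all(0 < v.maf <= 0.5 for v in pool)
        assert all(genome[v.chrom][v.pos] == v.major for v in pool)
        assert all(v.gc500 is not None and v.tss_dist is not None for v in pool)

    def test_designated_partners_in_strong_ld(self):
        from regprio.ld import dosage_r2

        cfg = SimulationConfig(seed=6, **SMALL)
        genome, genes = generate_genome(cfg, 6)
        _, genotypes, pairs = generate_snp_pool(cfg, genome, genes, 6)
        assert len(pairs) == cfg.ld_partner_pairs
        r2s = [dosage_r2(genotypes, a, b) for a, b in pairs]
        assert np.median(r2s) > 0.8


class TestMotifPlanting:
    def test_flagged_snps_score_100_major_and_lower_minor(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        genome, genes = generate_genome(cfg, 7)
        pool, _, _ = generate_snp_pool(cfg, genome, genes, 7)
        model = build_pwm(default_planted_pfm())
        flagged = []
        for v in pool:  # spaced loci so planted motifs cannot overlap
            if not flagged or v.pos - flagged[-1].pos > 200:
                flagged.append(v)
            if len(flagged) == 20:
                break
        genome2 = plant_motif_snps(genome, model, flagged)
        for v in flagged:
            s_maj, s_min = allelic_best_scores(model, genome2, v)
            assert s_maj == pytest.approx(100.0)
            assert s_min < s_maj

    def test_unflagged_diffs_centered_near_zero(self):
        from regprio.simulate import sync_alleles

        cfg = SimulationConfig(seed=8, chrom_sizes={"chr1": 1_000_000},
                               n_genes=20, n_pool_snps=600)
        genome, genes = generate_genome(cfg, 8)
        pool, _, _ = generate_snp_pool(cfg, genome, genes, 8)
        model = build_pwm(default_planted_pfm())
        genome2 = plant_motif_snps(genome, model, pool[:5])
        others = pool[5:505]
        sync_alleles(genome2, others, 8)
        diffs = [
            (lambda s: s[1] - s[0])(allelic_best_scores(model, genome2, v)) for v in others
        ]
        assert abs(np.mean(diffs)) < 2.0

    def test_motif_longer_than_flank_rejected(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        genome, genes = generate_genome(cfg, 9)
        pool, _, _ = generate_snp_pool(cfg, genome, genes, 9)
        with pytest.raises(ValueError, match="flank"):
            plant_motif_snps(genome, default_planted_pfm(), pool[:1], flank=8)


class TestLandscape:
    def test_flagged_snp_covered_in_cancer_only(self, small_bundle):
        flagged = small_bundle.truth[small_bundle.truth.condition_specific].snp_id
        by_id = {v.id: v for v in small_bundle.fg}
        for sid in flagged:
            v = by_id[sid]
            assert small_bundle.consensus["cancer"]["dnase"].contains(v.chrom, v.pos)
            for name, t in small_bundle.taf.items():
                assert t.contains(v.chrom, v.pos)

    def test_replicate_pairs_give_nonempty_consensus(self, small_bundle):
        for cond in small_bundle.consensus:
            for assay, t in small_bundle.consensus[cond].items():
                assert t.intervals, f"{cond}/{assay} consensus empty"


class TestHiCGeneration:
    def test_zero_between_rate_keeps_all_pairs_within_tads(self):
        cfg = SimulationConfig(seed=10, hic_lambda_out=0.0, n_hic_pairs=3000,
                               chrom_sizes={"chr1": 400_000})
        tads = make_tads(cfg, "chr1", 10)
        pairs = generate_hic(cfg, tads, 10)
        assert len(pairs) == 3000
        for p in pairs:
            t1 = next(t for t in tads if t.contains(p.pos1))
            assert t1.contains(p.pos2)

    def test_within_between_ratio_tracks_rates(self):
        cfg = SimulationConfig(seed=11, hic_lambda_in=5.0, hic_lambda_out=1.0,
                               n_hic_pairs=100_000, chrom_sizes={"chr1": 400_000})
        tads = make_tads(cfg, "chr1", 11)
        pairs = generate_hic(cfg, tads, 11)
        within = sum(
            1 for p in pairs
            if next(t for t in tads if t.contains(p.pos1)).contains(p.pos2)
        )
        ratio = within / (len(pairs) - within)
        assert 0.9 * 5.0 < ratio < 1.1 * 5.0


class TestExpression:
    def test_designated_genes_exceed_twofold_others_mostly_flat(self):
        cfg = SimulationConfig(seed=12, **SMALL)
        _, genes = generate_genome(cfg, 12)
        de_ids = {genes[0].gene_id, genes[1].gene_id}
        expr = generate_expression(cfg, genes, de_ids, 12)
        lfc = np.log2((expr.rpkm_cancer + 1) / (expr.rpkm_normal + 1))
        planted = expr.gene_id.isin(de_ids)
        assert np.all(np.abs(lfc[planted]) > 1.0)
        assert np.mean(np.abs(lfc[~planted]) > 1.0) < 0.10

    def test_flagged_snp_reports_nearby_de_genes(self, small_bundle):
        truth = small_bundle.truth
        flagged = set(truth[truth.condition_specific].snp_id)
        by_id = {v.id: v for v in small_bundle.fg}
        for sid in flagged:
            near = [
                g for g in small_bundle.genes
                if abs(g.tss - by_id[sid].pos) <= 200_000
            ]
            if near:
                out = nearby_differential_expression(by_id[sid], small_bundle.expression)
                assert {g for g, _ in out} >= {g.gene_id for g in near}


class TestBundleAndRoundTrip:
    def test_truth_covers_every_foreground_snp(self, small_bundle):
        assert set(small_bundle.truth.snp_id) == {v.id for v in small_bundle.fg}

    def test_written_dataset_reads_back(self, tmp_path, small_bundle):
        from regprio import io

        write_dataset(small_bundle, tmp_path)
        fg = io.read_snp_table(tmp_path / "foreground_snps.tsv")
        assert [(v.id, v.pos) for v in fg] == [(v.id, v.pos) for v in small_bundle.fg]
        genome = io.read_fasta(tmp_path / "genome.fa")
        v = small_bundle.fg[0]
        assert str(genome[v.chrom][v.pos]) == v.major
        track = io.read_peaks(
            tmp_path / "tracks" / "cancer_dnase_r1.narrowPeak", name="cancer_dnase"
        )
        orig = small_bundle.tracks["cancer"]["dnase"][0].intervals
        assert [(iv.chrom, iv.start, iv.end) for iv in track.intervals] == [
            (iv.chrom, iv.start, iv.end) for iv in orig
        ]
        for a, b in zip(track.intervals, orig):
            assert a.value == pytest.approx(b.value, rel=1e-5)
        tads = io.read_tads(tmp_path / "tads.bed")
        assert [(t.start, t.end) for t in tads] == [
            (t.start, t.end) for t in small_bundle.tads
        ]
        pairs = list(io.read_hic_pairs(tmp_path / "hic_pairs.tsv"))
        assert pairs == small_bundle.hic_pairs
        geno = io.read_genotype_table(tmp_path / "genotypes.tsv")
        assert np.array_equal(geno.dosages, small_bundle.genotypes.dosages)
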