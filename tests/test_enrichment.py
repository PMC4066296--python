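"""Covariate binning, matched resampling and empirical p/q-values."""
import numpy as np
import pytest

from regprio.annotate import Variant
from regprio.enrichment import (
    MatchedSampler,
    build_binning,
    draw_matched_set,
    enrichment_test,
    qvalues,
)
from regprio.intervals import FeatureTrack, GenomicInterval


def make_pool(rng, n=400, chrom="chr1"):
    pos = np.sort(rng.choice(np.arange(0, 10_000_000, 100), n, replace=False))
    pool = []
    for i, p in enumerate(pos):
        v = Variant(f"p{i}", chrom, int(p), "A", "G", maf=float(rng.uniform(0.01, 0.5)))
        v.gc500 = float(rng.uniform(0.2, 0.7))
        v.tss_dist = int(rng.integers(0, 500_000))
        pool.append(v)
    return pool


class TestBinning:
    def test_uniform_maf_edges_near_quantiles(self, rng):
        pool = make_pool(rng, 4000)
        binning = build_binning(pool)
        mafs = np.array([v.maf for v in pool])
        expected = np.quantile(mafs, np.arange(1, 20) / 20)
        assert np.allclose(binning.maf_edges, expected)

    def test_constant_attribute_single_occupied_bin(self, rng):
        pool = make_pool(rng, 100)
        for v in pool:
            v.gc500 = 0.5
        binning = build_binning(pool)
        bins = binning.assign_many(pool)
        assert len(set(bins[:, 1])) == 1

    def test_every_variant_gets_exactly_one_bin_triple(self, rng):
        pool = make_pool(rng, 300)
        binning = build_binning(pool)
        bins = binning.assign_many(pool)
        assert bins.shape == (300, 3)
        assert bins.min() >= 0 and bins.max() <= 19

    def test_tiny_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            build_binning(make_pool(rng, 10))

    def test_edge_ties_fall_to_lower_bin(self, rng):
        pool = make_pool(rng, 200)
        binning = build_binning(pool)
        v = pool[0]
        v.maf = float(binning.maf_edges[4])
        assert binning.assign(v)[0] == 4


class TestMatchedDraw:
    def test_joint_histogram_matches_exactly(self, rng):
        pool = make_pool(rng, 2000)
        binning = build_binning(pool)
        fg = [pool[i] for i in rng.choice(2000, 100, replace=False)]
        drawn = draw_matched_set(fg, pool, binning, rng)
        assert len(drawn) == len(fg)
        fg_hist = sorted(map(tuple, binning.assign_many(fg)))
        bg_hist = sorted(map(tuple, binning.assign_many(drawn)))
        assert fg_hist == bg_hist

    def test_same_seed_identical_draw(self, rng):
        pool = make_pool(rng, 1000)
        binning = build_binning(pool)
        fg = pool[:50]
        d1 = draw_matched_set(fg, pool, binning, 123)
        d2 = draw_matched_set(fg, pool, binning, 123)
        assert [v.id for v in d1] == [v.id for v in d2]

    def test_draw_has_no_duplicates(self, rng):
        pool = make_pool(rng, 1500)
        binning = build_binning(pool)
        fg = [pool[i] for i in rng.choice(1500, 200, replace=False)]
        drawn = draw_matched_set(fg, pool, binning, rng)
        ids = [v.id for v in drawn]
        assert len(ids) == len(set(ids))

    def test_mean_bin_counts_track_foreground(self, rng):
        pool = make_pool(rng, 3000)
        binning = build_binning(pool)
        fg = [pool[i] for i in rng.choice(3000, 60, replace=False)]
        sampler = MatchedSampler(pool, binning)
        fg_maf_bins = binning.assign_many(fg)[:, 0]
        fg_counts = np.bincount(fg_maf_bins, minlength=20)
        means = np.zeros(20)
        n_rep = 50
        for _ in range(n_rep):
            drawn = sampler.draw(fg, rng)
            means += np.bincount(binning.assign_many(drawn)[:, 0], minlength=20)
        assert np.allclose(means / n_rep, fg_counts)

    def test_impossible_bin_reports_its_key(self, rng):
        pool = make_pool(rng, 200)
        binning = build_binning(pool)
        # samplable pool restricted to the low-MAF half: a top-MAF-bin
        # foreground SNP has no members in its 3x3x3 neighbourhood
        bins = binning.assign_many(pool)
        low = [v for v, b in zip(pool, bins) if b[0] < 10]
        top = [v for v, b in zip(pool, bins) if b[0] == 19]
        sampler = MatchedSampler(low, binning)
        with pytest.raises(ValueError, match="covariate bin"):
            sampler.draw(top[:1], rng)


class TestEnrichmentTest:
    def test_feature_covering_everything_gives_p_one(self, rng):
        pool = make_pool(rng, 3000)
        binning = build_binning(pool)
        fg = pool[:40]
        rest = pool[40:]
        feature = FeatureTrack("all", [GenomicInterval("chr1", 0, 20_000_000)])
        res = enrichment_test(fg, rest, feature, binning, n_draws=50, rng=rng)
        assert res.fg_count == len(fg)
        assert np.all(res.bg_counts == len(fg))
        assert res.p_enrich == 1.0 and res.p_deplete == 1.0

    def test_foreground_only_feature_hits_add_one_floor(self, rng):
        pool = make_pool(rng, 3000)
        binning = build_binning(pool)
        fg = pool[:40]
        rest = pool[40:]
        feature = FeatureTrack(
            "fgonly", [GenomicInterval("chr1", v.pos, v.pos + 1) for v in fg]
        )
        res = enrichment_test(fg, rest, feature, binning, n_draws=100, rng=rng)
        assert res.fg_count == len(fg)
        assert res.p_enrich == pytest.approx(1 / 101)
        assert res.p_deplete == 1.0

    def test_invalid_n_draws(self, rng):
        pool = make_pool(rng, 100)
        binning = build_binning(pool)
        feature = FeatureTrack("f", [GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            enrichment_test(pool[:5], pool[5:], feature, binning, n_draws=0)

    def test_empirical_p_bounds(self, rng):
        pool = make_pool(rng, 3000)
        binning = build_binning(pool)
        fg = pool[:30]
        rest = pool[30:]
        feature = FeatureTrack(
            "f", [GenomicInterval("chr1", int(s), int(s) + 50_000)
                  for s in rng.integers(0, 9_000_000, 40)]
        )
        res = enrichment_test(fg, rest, feature, binning, n_draws=60, rng=rng)
        for p in (res.p_enrich, res.p_deplete):
            assert 0 < p <= 1


class TestQvalues:
    def test_all_ones_stay_one(self):
        assert np.all(qvalues([1.0] * 10) == 1.0)

    def test_empty_input(self):
        assert qvalues([]).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.0, 0.5])

    def test_bh_equivalence_with_pi0_fixed(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1.0, 1000)
        q = qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(q - bh)) < 1e-12

    def test_order_preserved_and_bounded(self, rng):
        p = rng.uniform(1e-4, 1.0, 200)
        q = qvalues(p)
        assert np.all(q <= 1.0) and np.all(q > 0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_pi0_estimate_near_one_under_null(self, rng):
        from regprio.enrichment import estimate_pi0

        p = rng.uniform(0.0001, 1.0, 5000)
        assert 0.8 <= estimate_pi0(p) <= 1.0
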