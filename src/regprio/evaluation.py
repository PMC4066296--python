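"""Study-level evaluation runs: calibration, power and recovery measurements.

Each function rebuilds its synthetic study from scratch under the given seed
and measures one operating characteristic of the pipeline: exact agreement
with independent oracles, type-I error and power of the matched resampling
test, recovery of planted motif-breaking alleles, Hi-C mass conservation,
and end-to-end recovery of a fully planted candidate SNP.
"""
from __future__ import annotations

import warnings

import numpy as np

from .enrichment import MatchedSampler, build_binning, enrichment_test, qvalues
from .hic import HiCPair, bin_hic_pairs
from .intervals import FeatureTrack, GenomicInterval, overlap_query
from .pipeline import prioritize_dataset
from .pwm import PFMRecord, build_pwm, differential_affinity_analysis, relative_score
from .rpi import relative_rp
from .simulate import (
    SimulationConfig,
    default_planted_pfm,
    enrichment_scenario,
    generate_genome,
    generate_snp_pool,
    generate_dataset,
    plant_motif_snps,
    split_planted_foreground,
    sync_alleles,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Exact oracles
# ---------------------------------------------------------------------------

def overlap_query_agreement(seed: int = 0, n_points: int = 1000, n_intervals: int = 500) -> float:
    """Fraction of random point queries on which the indexed overlap query
    agrees exactly with a brute-force scan of all intervals."""
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 100_000, n_intervals)
    lengths = rng.integers(1, 2_000, n_intervals)
    intervals = [
        GenomicInterval("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)
    ]
    track = FeatureTrack("t", intervals)
    agree = 0
    for pos in rng.integers(0, 105_000, n_points):
        brute = sorted(
            (iv for iv in intervals if iv.start <= pos < iv.end),
            key=lambda iv: (iv.start, iv.end),
        )
        agree += overlap_query(track, "chr1", int(pos)) == brute
    return agree / n_points


def _brute_force_relative(model, seq: str) -> float:
    span = model.max_score - model.min_score
    best = None
    L = model.length
    for i in range(len(seq) - L + 1):
        win = seq[i : i + L]
        for s in (win, win.translate(_COMPLEMENT)[::-1]):
            raw = 0.0
            for j, c in enumerate(s):
                raw += model.log_odds["ACGT".index(c), j]
            rel = 100.0 * (raw - model.min_score) / span
            if best is None or rel > best:
                best = rel
    return best


def pwm_scan_max_error(seed: int = 0, n_seqs: int = 100, n_pwms: int = 5) -> float:
    """Largest absolute deviation of the scanner from exhaustive window and
    strand enumeration over random sequences and random motifs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pwms):
        L = int(rng.integers(5, 9))
        model = build_pwm(
            PFMRecord("X", "X", rng.integers(0, 40, (4, L)).astype(float) + 1.0)
        )
        for _ in range(n_seqs // n_pwms):
            seq = "".join(rng.choice(list("ACGT"), 200))
            got, _, _ = relative_score(model, seq)
            worst = max(worst, abs(got - _brute_force_relative(model, seq)))
    return worst


def qvalue_bh_max_diff(seed: int = 0, n: int = 1000) -> float:
    """Largest deviation between q-values at pi0=1 and the independent
    Benjamini-Hochberg step-up construction."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(1e-6, 1.0, n)
    q = qvalues(p, pi0=1.0)
    # independent min-cummin construction
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    bh = np.empty(n)
    bh[order] = np.minimum(adj, 1.0)
    return float(np.max(np.abs(q - bh)))


def relative_rp_identity_error() -> float:
    """Worst deviation of the log-ratio index from its closed forms and from
    antisymmetry on a grid of inputs."""
    err = max(
        abs(relative_rp(0, 0) - 0.0),
        abs(relative_rp(1, 0) - 1.0),
        abs(relative_rp(3, 7) - (-1.0)),
    )
    for a in (0.0, 0.5, 2.0, 31.0):
        for b in (0.0, 1.0, 7.5, 100.0):
            err = max(err, abs(relative_rp(a, b) + relative_rp(b, a)))
    return float(err)


def hic_conservation(seed: int = 0, n_pairs: int = 100_000) -> tuple[int, int]:
    """(mass error, symmetry error) after binning random read pairs: the
    upper-triangle total must equal the accepted pair count and the matrix
    must be exactly symmetric."""
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, 2_000_000, (n_pairs, 2))
    pairs = [HiCPair("chr1", int(a), "chr1", int(b)) for a, b in pos]
    m = bin_hic_pairs(pairs, "chr1", 0, 2_000_000)
    iu = np.triu_indices(m.n_bins)
    mass_error = int(abs(m.counts[iu].sum() - n_pairs))
    symmetry_error = int(np.abs(m.counts - m.counts.T).sum())
    return mass_error, symmetry_error


# ---------------------------------------------------------------------------
# Resampling test calibration
# ---------------------------------------------------------------------------

def _enrichment_cfg(seed: int) -> SimulationConfig:
    """Array-scale pool over a long chromosome: joint covariate bins hold
    ~12 members each, so matched draws rarely need bin relaxation."""
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chr1": 20_000_000},
        n_pool_snps=100_000,
        n_genes=100,
        ld_partner_pairs=0,
    )


def enrichment_type1_rate(
    seed: int = 0,
    n_runs: int = 200,
    fg_size: int = 200,
    n_draws: int = 200,
    coverage: float = 0.2,
) -> float:
    """Fraction of null runs with p <= 0.05.

    Each run picks a uniform template from the pool, draws the null
    foreground with the same covariate matcher the background draws use
    (so foreground and background are exchangeable by construction), and
    tests it against a fixed feature.  The pool is large enough that every
    joint covariate bin holds many members, as in an array-scale pool.
    """
    cfg = _enrichment_cfg(seed)
    scenario = enrichment_scenario(cfg, coverage=coverage, rng=seed)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    n_pool = len(scenario.pool)
    sampler = MatchedSampler(scenario.pool, scenario.binning)
    for _ in range(n_runs):
        template = [scenario.pool[i] for i in rng.choice(n_pool, size=fg_size, replace=False)]
        fg = sampler.draw(template, rng)
        res = enrichment_test(
            fg, scenario.pool, scenario.feature, scenario.binning,
            n_draws=n_draws, rng=rng, sampler=sampler, match_to=template,
        )
        hits += res.p_enrich <= 0.05
    return hits / n_runs


def enrichment_power(
    seed: int = 0,
    n_runs: int = 100,
    fg_size: int = 200,
    frac_in_feature: float = 0.30,
    coverage: float = 0.05,
    n_draws: int = 200,
) -> float:
    """Detection rate (p <= 0.05) for foregrounds planted so that 30% of the
    SNPs fall in a feature covering 5% of the pool."""
    cfg = _enrichment_cfg(seed)
    scenario = enrichment_scenario(cfg, coverage=coverage, rng=seed)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    sampler = MatchedSampler(scenario.pool, scenario.binning)
    for _ in range(n_runs):
        fg, _rest = split_planted_foreground(scenario, fg_size, frac_in_feature, rng)
        res = enrichment_test(
            fg, scenario.pool, scenario.feature, scenario.binning,
            n_draws=n_draws, rng=rng, sampler=sampler,
        )
        hits += res.p_enrich <= 0.05
    return hits / n_runs


# ---------------------------------------------------------------------------
# Differential affinity recovery
# ---------------------------------------------------------------------------

def affinity_recovery_and_null_rate(
    seed: int = 0,
    n_planted: int = 200,
    n_null: int = 1000,
    n_bg: int = 2000,
) -> tuple[float, float]:
    """(recovery, null rate): the fraction of planted motif-breaking SNPs
    called differential, and the fraction of matched null SNPs reaching
    p <= 0.05 against the same kind of matched background."""
    cfg = SimulationConfig(
        seed=seed, chrom_sizes={"chr1": 4_000_000}, n_pool_snps=20_000, n_genes=80
    )
    rng = np.random.default_rng(seed)
    genome, genes = generate_genome(cfg, rng)
    pool, _, _ = generate_snp_pool(cfg, genome, genes, rng)
    model = build_pwm(default_planted_pfm())
    idx = rng.permutation(len(pool))
    planted = [pool[i] for i in idx[:n_planted]]
    null_fg = [pool[i] for i in idx[n_planted : n_planted + n_null]]
    rest = [pool[i] for i in idx[n_planted + n_null :]]
    genome = plant_motif_snps(genome, model, planted)
    sync_alleles(genome, null_fg + rest, rng)
    binning = build_binning(pool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_planted = differential_affinity_analysis(
            planted, genome, [model], rest, binning, n_bg=n_bg, rng=rng
        )
        res_null = differential_affinity_analysis(
            null_fg, genome, [model], rest, binning, n_bg=n_bg, rng=rng
        )
    recovery = float(np.mean([r.is_differential for r in res_planted]))
    null_rate = float(np.mean([r.p_emp <= 0.05 for r in res_null]))
    return recovery, null_rate


# ---------------------------------------------------------------------------
# End-to-end planted candidate recovery
# ---------------------------------------------------------------------------

def planted_candidate_rank_rate(seed: int = 0, n_seeds: int = 50, n_bg: int = 500) -> float:
    """Fraction of simulated studies in which the single fully planted
    candidate SNP is retained by the three-criteria filter and ranked first
    among the foreground decoys."""
    hits = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=seed + k)
        bundle = generate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, candidates, _, _ = prioritize_dataset(
                bundle, n_bg=n_bg, rng=seed + k + 10_000
            )
        planted = set(bundle.truth[bundle.truth.condition_specific].snp_id)
        hits += bool(candidates) and candidates[0].snp_id in planted
    return hits / n_seeds
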