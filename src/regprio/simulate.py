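"""Synthetic data generation for every pipeline stage.

The generator emulates the statistical structure of the real inputs — an
array-style SNP pool with MAF/GC/TSS covariates and LD partners, replicated
peak tracks with log-normal signal in a cancer and a normal condition, a
planted high-information motif whose minor allele breaks its most
informative column, TAF ChIP-seq datasets, block-structured Hi-C read pairs
over a TAD tiling, and an RPKM expression table — together with ground-truth
labels for parameter-recovery tests.  Everything is deterministic under the
configured seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, Variant, annotate_covariates
from .enrichment import CovariateBinning, build_binning
from .hic import HiCPair, TAD, tad_containing
from .intervals import FeatureTrack, GenomicInterval, merge_intervals, replicate_consensus
from .ld import GenotypeMatrix
from .pwm import BASES, PFMRecord, PWMModel, build_pwm

_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    Defaults describe the end-to-end recovery setting: one fully planted
    candidate SNP (cancer-only accessible chromatin, motif-breaking minor
    allele, TAF binding in every dataset) among decoy foreground SNPs, over
    a human-like 41% GC chromosome.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    gc: float = 0.41
    n_genes: int = 60
    n_samples: int = 120
    n_pool_snps: int = 10_000
    n_fg_snps: int = 501
    maf_low: float = 0.05
    maf_high: float = 0.5
    # LD structure: designated partner pairs sharing a founder haplotype
    ld_partner_pairs: int = 50
    ld_partner_max_dist: int = 100_000
    ld_flip_rate: float = 0.02
    # background peak landscape (per condition)
    peaks_per_mb: dict[str, float] = field(
        default_factory=lambda: {"dnase": 50.0, "h3k4me3": 20.0, "ctcf": 25.0}
    )
    peak_width: dict[str, int] = field(
        default_factory=lambda: {"dnase": 300, "h3k4me3": 1000, "ctcf": 400}
    )
    signal_mu: float = 1.5
    signal_sigma: float = 0.5
    replicate_jitter: int = 10
    # planted cancer-specific regulatory landscape
    n_planted_full: int = 1
    planted_peak_halfwidth: int = 200
    planted_signal_mu: float = 3.6
    planted_signal_sigma: float = 0.2
    # TAF ChIP-seq datasets
    n_taf_datasets: int = 8
    taf_peaks_per_mb: float = 30.0
    taf_peak_width: int = 300
    # Hi-C
    n_tads: int = 8
    tad_min_width: int = 100_000
    hic_lambda_in: float = 5.0
    hic_lambda_out: float = 1.0
    n_hic_pairs: int = 20_000
    # expression
    base_rpkm: float = 8.0
    rpkm_noise_sigma: float = 0.25
    de_fold: float = 6.0


def _rng(rng: np.random.Generator | int | None, cfg: SimulationConfig | None = None):
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = cfg.seed if cfg is not None else 0
    return np.random.default_rng(rng)


def default_planted_pfm() -> PFMRecord:
    """A 12-column motif of realistic strength (IC ~ 11 bits): four sharp
    flanking columns, one near-deterministic core column (the planted SNP
    site) and seven weakly constrained columns."""
    cols = [
        (2, 2, 95, 1),     # G
        (1, 2, 2, 95),     # T
        (2, 95, 2, 1),     # C
        (95, 2, 2, 1),     # A
        (100, 0, 0, 0),    # A   <- maximum-information column
        (60, 14, 13, 13),  # a
        (13, 60, 14, 13),  # c
        (13, 13, 60, 14),  # g
        (14, 13, 13, 60),  # t
        (60, 13, 14, 13),  # a
        (13, 14, 60, 13),  # g
        (13, 60, 13, 14),  # c
    ]
    return PFMRecord(matrix_id="SIM0001", tf_name="PlantedTF", counts=np.array(cols).T)


# ---------------------------------------------------------------------------
# Genome, genes, SNP pool
# ---------------------------------------------------------------------------

def generate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """I.i.d. sequence at the configured GC, with uniformly placed genes
    carrying exon/UTR structure."""
    rng = _rng(rng, cfg)
    gc = cfg.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome: dict[str, str] = {}
    for chrom, size in cfg.chrom_sizes.items():
        if size < 10_000:
            raise ValueError(f"{chrom}: chromosome size must be >= 10 kb")
        genome[chrom] = rng.choice(_BASE_BYTES, size=size, p=probs).tobytes().decode()
    genes: list[GeneModel] = []
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    for i in range(cfg.n_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        size = cfg.chrom_sizes[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 7))
        exon_lens = rng.integers(200, 801, n_exons)
        intron_lens = rng.integers(500, 3001, n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        start = int(rng.integers(1000, max(1001, size - span - 1000)))
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand=strand))
            pos += int(exon_lens[k]) + (int(intron_lens[k]) if k < n_exons - 1 else 0)
        first, last = exons[0], exons[-1]
        if strand == "+":
            tss, tts = first.start, last.end - 1
            utr5 = [GenomicInterval(chrom, first.start, first.start + 100, strand=strand)]
            utr3 = [GenomicInterval(chrom, last.end - 150, last.end, strand=strand)]
        else:
            tss, tts = last.end - 1, first.start
            utr5 = [GenomicInterval(chrom, last.end - 100, last.end, strand=strand)]
            utr3 = [GenomicInterval(chrom, first.start, first.start + 150, strand=strand)]
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                tts=tts,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genome, genes


def generate_snp_pool(
    cfg: SimulationConfig,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Variant], GenotypeMatrix, list[tuple[str, str]]]:
    """Array-style SNP pool with genotypes and designated LD partner pairs.

    Most SNPs have independent Hardy-Weinberg dosages at a uniform MAF; the
    designated partners copy their anchor's dosage vector with a small
    per-sample flip rate, achieving r^2 well above 0.8.
    """
    rng = _rng(rng, cfg)
    variants: list[Variant] = []
    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.round(sizes / sizes.sum() * cfg.n_pool_snps).astype(int)
    alloc[-1] = cfg.n_pool_snps - alloc[:-1].sum()
    k = 0
    for chrom, n in zip(chroms, alloc):
        size = cfg.chrom_sizes[chrom]
        positions = np.sort(rng.choice(np.arange(600, size - 600), size=n, replace=False))
        for pos in positions:
            major = genome[chrom][pos]
            minor = rng.choice([b for b in BASES if b != major])
            variants.append(
                Variant(
                    id=f"snp{k:06d}",
                    chrom=chrom,
                    pos=int(pos),
                    major=major,
                    minor=str(minor),
                    maf=float(rng.uniform(cfg.maf_low, cfg.maf_high)),
                )
            )
            k += 1
    mafs = np.array([v.maf for v in variants])
    dosages = rng.binomial(2, mafs[:, None], size=(len(variants), cfg.n_samples)).astype(np.int8)
    # LD partner pairs: copy the anchor's dosage vector with flip noise
    pairs: list[tuple[str, str]] = []
    pos_arr = np.array([v.pos for v in variants])
    chrom_arr = np.array([v.chrom for v in variants])
    available = np.ones(len(variants), dtype=bool)
    anchors = rng.permutation(len(variants))
    for i in anchors:
        if len(pairs) >= cfg.ld_partner_pairs:
            break
        if not available[i]:
            continue
        near = np.flatnonzero(
            available
            & (chrom_arr == chrom_arr[i])
            & (np.abs(pos_arr - pos_arr[i]) <= cfg.ld_partner_max_dist)
            & (pos_arr != pos_arr[i])
        )
        if near.size == 0:
            continue
        j = int(rng.choice(near))
        if np.std(dosages[i]) == 0:
            # monomorphic anchor in this cohort: no defined r^2, skip
            available[i] = False
            continue
        variants[j].maf = variants[i].maf
        # flip noise, retried so the realized r^2 stays above the LD threshold
        anchor = dosages[i].astype(float)
        for _ in range(20):
            copied = dosages[i].copy()
            flips = rng.random(cfg.n_samples) < cfg.ld_flip_rate
            copied[flips] = rng.binomial(2, variants[i].maf, size=int(flips.sum()))
            if np.std(copied) > 0 and np.corrcoef(anchor, copied.astype(float))[0, 1] ** 2 >= 0.85:
                break
        else:
            copied = dosages[i].copy()
        dosages[j] = copied
        available[i] = available[j] = False
        pairs.append((variants[i].id, variants[j].id))
    genotypes = GenotypeMatrix(
        variants=variants, samples=[f"s{t:03d}" for t in range(cfg.n_samples)], dosages=dosages
    )
    annotate_covariates(variants, genome, genes)
    return variants, genotypes, pairs


def split_foreground(
    pool: Sequence[Variant], n_fg: int, rng: np.random.Generator | int = 0
) -> tuple[list[Variant], list[Variant]]:
    """Uniformly split off a foreground set; returns (foreground, remaining pool)."""
    rng = _rng(rng)
    idx = rng.choice(len(pool), size=n_fg, replace=False)
    mask = np.zeros(len(pool), dtype=bool)
    mask[idx] = True
    fg = [pool[i] for i in np.flatnonzero(mask)]
    rest = [pool[i] for i in np.flatnonzero(~mask)]
    return fg, rest


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motif_snps(
    genome: Mapping[str, str],
    pfm: PFMRecord | PWMModel,
    variants: Sequence[Variant],
    flank: int = 30,
) -> dict[str, str]:
    """Write the motif consensus into the genome at each flagged SNP.

    The motif is aligned so its maximum-information column sits on the SNP;
    the major allele is set to the consensus base there and the minor allele
    to the worst-scoring base, so the minor allele breaks the motif's most
    informative position.  Returns the modified genome.
    """
    model = build_pwm(pfm) if isinstance(pfm, PFMRecord) else pfm
    L = model.length
    if L > flank:
        raise ValueError(f"motif length {L} exceeds the scanning flank {flank}")
    probs = model.background[:, None] * np.exp2(model.log_odds)
    col_ic = 2.0 + np.where(probs > 0, probs * np.log2(probs), 0.0).sum(axis=0)
    top = int(np.argmax(col_ic))
    consensus = model.consensus
    worst = BASES[int(np.argmin(model.log_odds[:, top]))]
    editable = {c: bytearray(str(genome[c][:]).encode()) for c in genome}
    for v in variants:
        start = v.pos - top
        if start < 0 or start + L > len(editable[v.chrom]):
            raise ValueError(f"{v.id}: planted motif would extend beyond the chromosome")
        editable[v.chrom][start : start + L] = consensus.encode()
        v.major = consensus[top]
        v.minor = worst if worst != v.major else BASES[(BASE_INDEX_OF[v.major] + 1) % 4]
    # second pass: overlapping motif copies may have overwritten an earlier
    # SNP's base with a non-core consensus column; re-assert the core base
    for v in variants:
        editable[v.chrom][v.pos : v.pos + 1] = v.major.encode()
    return {c: b.decode() for c, b in editable.items()}


BASE_INDEX_OF = {b: i for i, b in enumerate(BASES)}


def sync_alleles(
    genome: Mapping[str, str], variants: Sequence[Variant], rng: np.random.Generator | int = 0
) -> None:
    """Re-align declared major alleles with the (possibly edited) genome."""
    rng = _rng(rng)
    for v in variants:
        base = genome[v.chrom][v.pos].upper()
        if base != v.major:
            v.major = base
            if v.minor == v.major:
                v.minor = str(rng.choice([b for b in BASES if b != v.major]))


# ---------------------------------------------------------------------------
# Peak landscape
# ---------------------------------------------------------------------------

def _background_peaks(
    cfg: SimulationConfig, width: int, per_mb: float, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    peaks = []
    for chrom, size in cfg.chrom_sizes.items():
        n = int(round(per_mb * size / 1e6))
        starts = rng.integers(0, max(1, size - 2 * width), size=n)
        for s in np.sort(starts):
            w = max(50, int(rng.normal(width, 0.15 * width)))
            peaks.append((chrom, int(s), min(int(s) + w, size)))
    return peaks


def _replicate_pair(
    cfg: SimulationConfig,
    name: str,
    base_peaks: list[tuple[str, int, int]],
    signal_mu: Sequence[float],
    rng: np.random.Generator,
) -> list[FeatureTrack]:
    """Two replicates of one assay: jittered copies of the base peak set with
    independent log-normal signals.  ``signal_mu`` gives the log-mean per peak."""
    reps = []
    for r in (1, 2):
        intervals = []
        for (chrom, s, e), mu in zip(base_peaks, signal_mu):
            j1 = int(rng.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1))
            j2 = int(rng.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1))
            start = max(0, s + j1)
            end = max(start + 1, e + j2)
            value = float(rng.lognormal(mu, cfg.signal_sigma))
            intervals.append(GenomicInterval(chrom, start, end, value=value))
        reps.append(FeatureTrack(name=name, intervals=intervals, replicate_id=f"r{r}"))
    return reps


def plant_regulatory_landscape(
    cfg: SimulationConfig,
    fg: Sequence[Variant],
    flagged_ids: set[str],
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, dict[str, list[FeatureTrack]]], dict[str, list[FeatureTrack]]]:
    """Replicated peak tracks per condition plus TAF datasets.

    SNPs in ``flagged_ids`` receive a strong DNase peak (and peaks in every
    TAF dataset) in the cancer condition only; no H3K4me3 is placed there, so
    the planted site classifies as a potential enhancer.  All other peaks are
    background noise at the configured density in both conditions.
    """
    rng = _rng(rng, cfg)
    flagged = [v for v in fg if v.id in flagged_ids]
    tracks: dict[str, dict[str, list[FeatureTrack]]] = {}
    hw = cfg.planted_peak_halfwidth
    for condition in ("cancer", "normal"):
        tracks[condition] = {}
        for assay, per_mb in cfg.peaks_per_mb.items():
            base = _background_peaks(cfg, cfg.peak_width[assay], per_mb, rng)
            mus = [cfg.signal_mu] * len(base)
            if condition == "cancer" and assay == "dnase":
                for v in flagged:
                    base.append((v.chrom, max(0, v.pos - hw), v.pos + hw))
                    mus.append(cfg.planted_signal_mu)
            tracks[condition][assay] = _replicate_pair(
                cfg, f"{condition}_{assay}", base, mus, rng
            )
    taf: dict[str, list[FeatureTrack]] = {}
    for k in range(cfg.n_taf_datasets):
        base = _background_peaks(cfg, cfg.taf_peak_width, cfg.taf_peaks_per_mb, rng)
        mus = [cfg.signal_mu] * len(base)
        for v in flagged:
            base.append((v.chrom, max(0, v.pos - hw), v.pos + hw))
            mus.append(cfg.planted_signal_mu)
        taf[f"taf{k:02d}"] = _replicate_pair(cfg, f"taf{k:02d}", base, mus, rng)
    return tracks, taf


# ---------------------------------------------------------------------------
# Hi-C and expression
# ---------------------------------------------------------------------------

def make_tads(
    cfg: SimulationConfig, chrom: str, rng: np.random.Generator | int | None = None
) -> list[TAD]:
    """A TAD tiling of the chromosome with the configured minimum width."""
    rng = _rng(rng, cfg)
    size = cfg.chrom_sizes[chrom]
    n = cfg.n_tads
    # clamp the minimum width so any chromosome admits an n-domain tiling
    min_width = min(cfg.tad_min_width, size // (2 * n))
    if min_width < 1:
        raise ValueError("chromosome too small for the requested TAD tiling")
    slack = size - n * min_width
    widths = min_width + rng.multinomial(slack, np.full(n, 1.0 / n))
    bounds = np.concatenate(([0], np.cumsum(widths)))
    return [TAD(chrom, int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def generate_hic(
    cfg: SimulationConfig,
    tads: Sequence[TAD],
    rng: np.random.Generator | int | None = None,
) -> list[HiCPair]:
    """Read pairs with both ends in one TAD at rate lambda_in and spanning
    TADs at lambda_out (per-pair category odds lambda_in : lambda_out)."""
    rng = _rng(rng, cfg)
    chrom = tads[0].chrom
    lengths = np.array([t.end - t.start for t in tads], dtype=float)
    weights = lengths / lengths.sum()
    p_in = cfg.hic_lambda_in / (cfg.hic_lambda_in + cfg.hic_lambda_out)
    pairs: list[HiCPair] = []
    for _ in range(cfg.n_hic_pairs):
        if rng.random() < p_in:
            t = tads[int(rng.choice(len(tads), p=weights))]
            a = int(rng.integers(t.start, t.end))
            b = int(rng.integers(t.start, t.end))
        else:
            i = int(rng.choice(len(tads), p=weights))
            j = int(rng.choice(len(tads), p=weights))
            while j == i and len(tads) > 1:
                j = int(rng.choice(len(tads), p=weights))
            a = int(rng.integers(tads[i].start, tads[i].end))
            b = int(rng.integers(tads[j].start, tads[j].end))
        pairs.append(HiCPair(chrom, a, chrom, b))
    return pairs


def generate_expression(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    de_gene_ids: set[str],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """RPKM pairs: multiplicative log-normal noise around a common baseline,
    with the configured fold change planted for designated genes."""
    rng = _rng(rng, cfg)
    rows = []
    for g in genes:
        base = rng.lognormal(math.log(cfg.base_rpkm), 0.6)
        normal = base * rng.lognormal(0.0, cfg.rpkm_noise_sigma)
        cancer = base * rng.lognormal(0.0, cfg.rpkm_noise_sigma)
        if g.gene_id in de_gene_ids:
            cancer *= cfg.de_fold
        rows.append((g.gene_id, g.chrom, g.tss, cancer, normal))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "rpkm_cancer", "rpkm_normal"]
    )


# ---------------------------------------------------------------------------
# Full bundles and scenario helpers
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Everything one pipeline run consumes, plus ground truth."""

    cfg: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    pool: list[Variant]
    fg: list[Variant]
    genotypes: GenotypeMatrix
    ld_pairs: list[tuple[str, str]]
    tracks: dict[str, dict[str, list[FeatureTrack]]]
    consensus: dict[str, dict[str, FeatureTrack]]
    taf_reps: dict[str, list[FeatureTrack]]
    taf: dict[str, FeatureTrack]
    tads: list[TAD]
    hic_pairs: list[HiCPair]
    expression: pd.DataFrame
    truth: pd.DataFrame
    pfm: PFMRecord


def generate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | int | None = None
) -> SimBundle:
    """Generate the complete synthetic study under one seed."""
    rng = _rng(rng, cfg)
    genome, genes = generate_genome(cfg, rng)
    pool_all, genotypes, ld_pairs = generate_snp_pool(cfg, genome, genes, rng)
    fg, pool = split_foreground(pool_all, cfg.n_fg_snps, rng)
    flagged = (
        [fg[i] for i in rng.choice(len(fg), size=cfg.n_planted_full, replace=False)]
        if cfg.n_planted_full
        else []
    )
    flagged_ids = {v.id for v in flagged}
    pfm = default_planted_pfm()
    if flagged:
        genome = plant_motif_snps(genome, pfm, flagged)
        sync_alleles(genome, [v for v in pool_all if v.id not in flagged_ids], rng)
    annotate_covariates(pool_all, genome, genes)
    tracks, taf_reps = plant_regulatory_landscape(cfg, fg, flagged_ids, rng)
    consensus = {
        cond: {assay: replicate_consensus(reps) for assay, reps in assays.items()}
        for cond, assays in tracks.items()
    }
    taf = {name: replicate_consensus(reps) for name, reps in taf_reps.items()}
    chrom = sorted(cfg.chrom_sizes)[0]
    tads = make_tads(cfg, chrom, rng)
    hic_pairs = generate_hic(cfg, tads, rng)
    de_ids = {
        g.gene_id
        for g in genes
        for v in flagged
        if g.chrom == v.chrom and abs(g.tss - v.pos) <= 200_000
    }
    expression = generate_expression(cfg, genes, de_ids, rng)
    truth = pd.DataFrame(
        {
            "snp_id": [v.id for v in fg],
            "condition_specific": [v.id in flagged_ids for v in fg],
            "motif": [v.id in flagged_ids for v in fg],
            "tad_id": [
                (lambda t: -1 if t is None else tads.index(t))(tad_containing(v, tads))
                for v in fg
            ],
        }
    )
    return SimBundle(
        cfg=cfg,
        genome=genome,
        genes=genes,
        pool=pool,
        fg=fg,
        genotypes=genotypes,
        ld_pairs=ld_pairs,
        tracks=tracks,
        consensus=consensus,
        taf_reps=taf_reps,
        taf=taf,
        tads=tads,
        hic_pairs=hic_pairs,
        expression=expression,
        truth=truth,
        pfm=pfm,
    )


@dataclass
class EnrichmentScenario:
    """A pool with covariates and one feature track for resampling tests."""

    genome: dict[str, str]
    genes: list[GeneModel]
    pool: list[Variant]
    binning: CovariateBinning
    feature: FeatureTrack


def enrichment_scenario(
    cfg: SimulationConfig,
    coverage: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentScenario:
    """Build a pool and a feature covering ``coverage`` of the pool SNPs.

    The feature is the merged union of 1 kb windows around a random subset of
    pool SNPs, so its SNP coverage is exact by construction.
    """
    rng = _rng(rng, cfg)
    genome, genes = generate_genome(cfg, rng)
    pool, _, _ = generate_snp_pool(cfg, genome, genes, rng)
    chroms = sorted(cfg.chrom_sizes)
    if len(chroms) != 1:
        raise ValueError("enrichment scenarios use a single-chromosome landscape")
    chrom = chroms[0]
    size = cfg.chrom_sizes[chrom]
    # accumulate random 1 kb windows until the feature covers the requested
    # fraction of pool SNP positions (overshoot is at most one window's SNPs)
    pos = np.array([v.pos for v in pool])
    target = int(round(coverage * len(pool)))
    covered = np.zeros(len(pool), dtype=bool)
    windows: list[GenomicInterval] = []
    while covered.sum() < target:
        s = int(rng.integers(0, size - 1000))
        windows.append(GenomicInterval(chrom, s, s + 1000))
        covered |= (pos >= s) & (pos < s + 1000)
    feature = FeatureTrack(name="feature", intervals=merge_intervals(windows))
    return EnrichmentScenario(
        genome=genome, genes=genes, pool=pool, binning=build_binning(pool), feature=feature
    )


def split_planted_foreground(
    scenario: EnrichmentScenario,
    n_fg: int,
    frac_in_feature: float,
    rng: np.random.Generator | int = 0,
) -> tuple[list[Variant], list[Variant]]:
    """Foreground with a planted fraction inside the feature; returns
    (foreground, remaining pool)."""
    rng = _rng(rng)
    inside = scenario.feature.contains_many(
        scenario.pool[0].chrom, np.array([v.pos for v in scenario.pool])
    ) if len({v.chrom for v in scenario.pool}) == 1 else np.array(
        [scenario.feature.contains(v.chrom, v.pos) for v in scenario.pool]
    )
    in_idx = np.flatnonzero(inside)
    out_idx = np.flatnonzero(~inside)
    n_in = int(round(frac_in_feature * n_fg))
    pick = np.concatenate(
        [
            rng.choice(in_idx, size=n_in, replace=False),
            rng.choice(out_idx, size=n_fg - n_in, replace=False),
        ]
    )
    mask = np.zeros(len(scenario.pool), dtype=bool)
    mask[pick] = True
    fg = [scenario.pool[i] for i in np.flatnonzero(mask)]
    rest = [scenario.pool[i] for i in np.flatnonzero(~mask)]
    return fg, rest


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(bundle: SimBundle, outdir: str | Path) -> None:
    """Write every format the pipeline consumes, plus ground truth."""
    from . import io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_fasta(bundle.genome, out / "genome.fa")
    io.write_bed12_genes(bundle.genes, out / "genes.bed12")
    io.write_snp_table(bundle.fg, out / "foreground_snps.tsv")
    io.write_snp_table(bundle.pool, out / "pool_snps.tsv")
    io.write_genotype_table(bundle.genotypes, out / "genotypes.tsv")
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for cond, assays in bundle.tracks.items():
        for assay, reps in assays.items():
            for rep in reps:
                io.write_peaks(
                    rep, tracks_dir / f"{cond}_{assay}_{rep.replicate_id}.narrowPeak"
                )
    taf_dir = out / "taf"
    taf_dir.mkdir(exist_ok=True)
    for name, reps in bundle.taf_reps.items():
        for rep in reps:
            io.write_peaks(rep, taf_dir / f"{name}_{rep.replicate_id}.narrowPeak")
    io.write_tads(bundle.tads, out / "tads.bed")
    io.write_hic_pairs(bundle.hic_pairs, out / "hic_pairs.tsv")
    io.write_expression(bundle.expression, out / "expression.tsv")
    io.write_pfm_collection([bundle.pfm], out / "motifs.pfm")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
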