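"""Covariate-matched resampling test of SNP-set enrichment in feature tracks.

Foreground SNPs are compared with background sets drawn from an array-style
pool so that the joint distribution over three covariates (minor allele
frequency, +/-500 bp GC content, distance to the nearest TSS), each cut into
20 pool-percentile bins, matches the foreground exactly.  Empirical p-values
use the add-one rule and are corrected across features with Storey q-values.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .annotate import Variant
from .intervals import FeatureTrack

N_BINS_DEFAULT = 20


@dataclass
class CovariateBinning:
    """Percentile bin edges for (maf, gc500, tss_dist); ties fall to the lower bin."""

    maf_edges: np.ndarray
    gc_edges: np.ndarray
    tss_edges: np.ndarray
    n_bins: int = N_BINS_DEFAULT

    def assign(self, v: Variant) -> tuple[int, int, int]:
        if v.gc500 is None or v.tss_dist is None:
            raise ValueError(f"{v.id}: covariates not annotated")
        return (
            int(np.searchsorted(self.maf_edges, v.maf, side="left")),
            int(np.searchsorted(self.gc_edges, v.gc500, side="left")),
            int(np.searchsorted(self.tss_edges, v.tss_dist, side="left")),
        )

    def assign_many(self, variants: Sequence[Variant]) -> np.ndarray:
        maf = np.array([v.maf for v in variants], dtype=float)
        gc = np.array([v.gc500 for v in variants], dtype=float)
        tss = np.array([v.tss_dist for v in variants], dtype=float)
        if np.any(np.isnan(gc)) or np.any(np.isnan(tss)):
            raise ValueError("covariates not annotated on every variant")
        return np.column_stack(
            [
                np.searchsorted(self.maf_edges, maf, side="left"),
                np.searchsorted(self.gc_edges, gc, side="left"),
                np.searchsorted(self.tss_edges, tss, side="left"),
            ]
        )


def build_binning(pool: Sequence[Variant], n_bins: int = N_BINS_DEFAULT) -> CovariateBinning:
    """Equal-probability percentile bins per covariate from the pool."""
    if len(pool) < n_bins:
        raise ValueError(f"pool of {len(pool)} too small for {n_bins} bins")
    q = np.arange(1, n_bins) / n_bins

    def edges(vals: list[float]) -> np.ndarray:
        a = np.asarray(vals, dtype=float)
        if np.any(np.isnan(a)):
            raise ValueError("covariates not annotated on every pool variant")
        return np.quantile(a, q)

    return CovariateBinning(
        maf_edges=edges([v.maf for v in pool]),
        gc_edges=edges([v.gc500 for v in pool]),
        tss_edges=edges([float(v.tss_dist) for v in pool]),
        n_bins=n_bins,
    )


class MatchedSampler:
    """Reusable covariate-matched sampler over a fixed pool.

    Each draw reproduces the foreground's joint (maf, gc, tss) bin histogram,
    sampling without replacement within each joint bin.  A bin with too few
    pool members is relaxed to its 3x3x3 bin neighbourhood; if that is still
    insufficient the draw fails, naming the bin.
    """

    def __init__(self, pool: Sequence[Variant], binning: CovariateBinning):
        self.pool = list(pool)
        self.binning = binning
        self._index_of = {v.id: i for i, v in enumerate(self.pool)}
        bins = binning.assign_many(self.pool)
        grouped: dict[tuple[int, int, int], list[int]] = {}
        for i, row in enumerate(bins):
            grouped.setdefault((int(row[0]), int(row[1]), int(row[2])), []).append(i)
        self._groups: dict[tuple[int, int, int], np.ndarray] = {
            k: np.array(v, dtype=int) for k, v in grouped.items()
        }
        self._neighbourhoods: dict[tuple[int, int, int], np.ndarray] = {}

    def _neighbourhood(self, key: tuple[int, int, int]) -> np.ndarray:
        if key not in self._neighbourhoods:
            n = self.binning.n_bins
            parts = [
                self._groups[k]
                for k in product(*(range(max(0, c - 1), min(n, c + 2)) for c in key))
                if k in self._groups
            ]
            self._neighbourhoods[key] = (
                np.concatenate(parts) if parts else np.array([], dtype=int)
            )
        return self._neighbourhoods[key]

    def draw(
        self,
        fg: Sequence[Variant],
        rng: np.random.Generator | int = 0,
        exclude: Sequence[Variant] | None = None,
    ) -> list[Variant]:
        """One matched draw.  ``exclude`` marks pool members (e.g. the
        foreground itself) as unavailable, equivalent to removing them from
        the samplable pool."""
        rng = (
            np.random.default_rng(rng)
            if not isinstance(rng, np.random.Generator)
            else rng
        )
        fg_hist = Counter(map(tuple, self.binning.assign_many(fg)))
        used = np.zeros(len(self.pool), dtype=bool)
        if exclude is not None:
            for v in exclude:
                idx = self._index_of.get(v.id)
                if idx is not None:
                    used[idx] = True
        chosen: list[int] = []
        for key in sorted(fg_hist):
            k = fg_hist[key]
            members = self._groups.get(key, np.array([], dtype=int))
            cands = members[~used[members]]
            if cands.size < k:
                members = self._neighbourhood(key)
                cands = members[~used[members]]
                if cands.size < k:
                    raise ValueError(
                        f"cannot draw {k} matched SNPs for covariate bin {key}: "
                        f"only {cands.size} pool members in its 3x3x3 neighbourhood"
                    )
            pick = rng.choice(cands, size=k, replace=False)
            chosen.extend(int(i) for i in pick)
            used[pick] = True
        return [self.pool[i] for i in chosen]


def draw_matched_set(
    fg: Sequence[Variant],
    pool: Sequence[Variant],
    binning: CovariateBinning,
    rng: np.random.Generator | int = 0,
) -> list[Variant]:
    """One covariate-matched background set of ``len(fg)`` pool SNPs."""
    return MatchedSampler(pool, binning).draw(fg, rng)


@dataclass
class EnrichmentResult:
    """Foreground overlap count against its matched-background distribution."""

    feature_name: str
    fg_count: int
    bg_counts: np.ndarray
    p_enrich: float
    p_deplete: float
    q_value: float = float("nan")


def enrichment_test(
    fg: Sequence[Variant],
    pool: Sequence[Variant],
    feature: FeatureTrack,
    binning: CovariateBinning,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    sampler: MatchedSampler | None = None,
    match_to: Sequence[Variant] | None = None,
    exclude: Sequence[Variant] | None = None,
) -> EnrichmentResult:
    """Empirical enrichment (and depletion) of the foreground in one feature.

    p_enrich = (1 + #{background count >= foreground count}) / (n_draws + 1);
    p_deplete is symmetric with <=.  Pass a prebuilt ``sampler`` to amortise
    pool indexing across features.  ``match_to`` overrides the covariate
    histogram the background draws reproduce (defaults to the foreground);
    ``exclude`` marks pool members as unavailable to the draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sampler is None:
        sampler = MatchedSampler(pool, binning)
    template = fg if match_to is None else match_to
    fg_count = feature.count_overlapping(fg)
    bg_counts = np.array(
        [
            feature.count_overlapping(sampler.draw(template, rng, exclude=exclude))
            for _ in range(n_draws)
        ]
    )
    return EnrichmentResult(
        feature_name=feature.name,
        fg_count=fg_count,
        bg_counts=bg_counts,
        p_enrich=float((1 + np.sum(bg_counts >= fg_count)) / (n_draws + 1)),
        p_deplete=float((1 + np.sum(bg_counts <= fg_count)) / (n_draws + 1)),
    )


def run_enrichment(
    fg: Sequence[Variant],
    pool: Sequence[Variant],
    features: Sequence[FeatureTrack],
    binning: CovariateBinning | None = None,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
) -> list[EnrichmentResult]:
    """Test one foreground against many features and attach q-values."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if binning is None:
        binning = build_binning(pool)
    sampler = MatchedSampler(pool, binning)
    results = [
        enrichment_test(fg, pool, f, binning, n_draws=n_draws, rng=rng, sampler=sampler)
        for f in features
    ]
    if results:
        qs = qvalues([r.p_enrich for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def estimate_pi0(pvals: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is evaluated on
    lambda = 0.05, 0.10, ..., 0.95 and smoothed with a cubic fit; the value
    at the largest lambda, clamped into (0, 1], is returned.
    """
    p = np.asarray(pvals, dtype=float)
    lams = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array([np.mean(p > lam) / (1 - lam) for lam in lams])
    fit = np.polynomial.Polynomial.fit(lams, pi0s, 3)
    return float(np.clip(fit(lams[-1]), 1e-8, 1.0))


def qvalues(pvals: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a vector of p-values in (0, 1].

    With ``pi0`` fixed at 1 this reduces to the Benjamini-Hochberg step-up
    adjustment (min-cummin form).  By default pi0 is estimated with the
    smoother method.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
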