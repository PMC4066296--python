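"""Three-criteria prioritization of candidate regulatory SNPs.

A candidate must (1) show a large relative regulatory potential between
conditions, (2) carry at least one significant differential TF-affinity
call, and (3) overlap sufficiently many TAF ChIP-seq datasets.  The two
numeric thresholds default to the 95th percentile of the examined SNPs and
can be overridden (the reference analysis used +/-5 and 6).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pwm import AffinityResult
from .rpi import RPIRecord


@dataclass
class CandidateRecord:
    """Per-SNP evidence across the three criteria plus the ranking key."""

    snp_id: str
    rel_rp: float
    affinity_calls: list[tuple[str, str, float]] = field(default_factory=list)
    taf_count: int = 0
    passes_all: bool = False

    @property
    def min_p(self) -> float:
        return min((p for _, _, p in self.affinity_calls), default=math.inf)

    @property
    def rank_key(self) -> tuple:
        return (-self.taf_count, -abs(self.rel_rp), self.min_p, self.snp_id)


def build_candidates(
    rpi_records: Sequence[RPIRecord],
    affinity_results: Sequence[AffinityResult],
) -> list[CandidateRecord]:
    """Join per-SNP regulatory potential with differential-affinity calls."""
    calls: dict[str, list[tuple[str, str, float]]] = {}
    for r in affinity_results:
        if r.is_differential:
            calls.setdefault(r.snp_id, []).append((r.matrix_id, r.direction, r.p_emp))
    return [
        CandidateRecord(
            snp_id=r.snp_id,
            rel_rp=r.rel_rp,
            affinity_calls=sorted(calls.get(r.snp_id, [])),
            taf_count=r.taf_count,
        )
        for r in rpi_records
    ]


def derive_thresholds(
    records: Sequence[CandidateRecord],
    pct: float = 95.0,
    rp_threshold: float | None = None,
    taf_threshold: int | None = None,
) -> tuple[float, int]:
    """Thresholds at the ``pct``-th percentile of all examined SNPs.

    The regulatory-potential threshold is the percentile of |rel_rp|; the TAF
    threshold is the percentile of the dataset-overlap count, rounded up.
    Explicit overrides are returned verbatim.
    """
    if rp_threshold is not None and taf_threshold is not None:
        return float(rp_threshold), int(taf_threshold)
    if len(records) < 20:
        raise ValueError(
            "fewer than 20 records: percentile thresholds are unstable, "
            "pass explicit rp_threshold/taf_threshold"
        )
    rp = float(np.percentile([abs(r.rel_rp) for r in records], pct))
    taf = int(math.ceil(np.percentile([r.taf_count for r in records], pct)))
    if rp_threshold is not None:
        rp = float(rp_threshold)
    if taf_threshold is not None:
        taf = int(taf_threshold)
    return rp, taf


def three_criteria_filter(
    records: Sequence[CandidateRecord],
    rp_threshold: float,
    taf_threshold: int,
) -> list[CandidateRecord]:
    """Retain SNPs meeting all three criteria, ranked by evidence.

    Criteria (threshold comparisons are inclusive): |rel_rp| >= rp_threshold;
    at least one differential-affinity call; taf_count >= taf_threshold.
    Ranking: TAF count desc, |rel_rp| desc, best affinity p asc, SNP id.
    """
    kept = []
    for r in records:
        r.passes_all = (
            abs(r.rel_rp) >= rp_threshold
            and len(r.affinity_calls) >= 1
            and r.taf_count >= taf_threshold
        )
        if r.passes_all:
            kept.append(r)
    kept.sort(key=lambda r: r.rank_key)
    return kept
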