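"""End-to-end orchestration: from a simulated (or loaded) study bundle to the
ranked three-criteria candidate list."""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .enrichment import build_binning
from .prioritize import CandidateRecord, build_candidates, derive_thresholds, three_criteria_filter
from .pwm import AffinityResult, PWMModel, build_pwm, differential_affinity_analysis
from .rpi import RPIRecord, build_rpi_records
from .simulate import SimBundle


def prioritize_dataset(
    bundle: SimBundle,
    pwms: Sequence[PWMModel] | None = None,
    n_bg: int = 500,
    rng: np.random.Generator | int = 0,
    rp_threshold: float | None = None,
    taf_threshold: int | None = None,
) -> tuple[list[CandidateRecord], list[CandidateRecord], list[RPIRecord], list[AffinityResult]]:
    """Score every foreground SNP on the three criteria and rank candidates.

    Returns (all per-SNP records, retained ranked candidates, RPI records,
    affinity results).  Thresholds default to the 95th percentile of the
    examined SNPs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if pwms is None:
        pwms = [build_pwm(bundle.pfm)]
    binning = build_binning(bundle.pool)
    affinity = differential_affinity_analysis(
        bundle.fg, bundle.genome, pwms, bundle.pool, binning, n_bg=n_bg, rng=rng
    )
    rpi_records = build_rpi_records(
        bundle.fg,
        cancer=bundle.consensus["cancer"],
        normal=bundle.consensus["normal"],
        taf_datasets=bundle.taf,
        expression=bundle.expression,
    )
    records = build_candidates(rpi_records, affinity)
    rp_thr, taf_thr = derive_thresholds(
        records, rp_threshold=rp_threshold, taf_threshold=taf_threshold
    )
    candidates = three_criteria_filter(records, rp_thr, taf_thr)
    return records, candidates, rpi_records, affinity
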