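"""Position weight matrix construction, 0-100 relative log-odds scanning,
allelic best scores around SNPs, and the matched-background empirical test
for differential transcription factor binding affinity.

Scoring model
-------------
A position frequency matrix (base counts per motif column) is smoothed with a
pseudocount split by background base frequencies:

    p[b, j] = (count[b, j] + pc * bg[b]) / (colsum[j] + pc)

Log-odds are ``log2(p / bg)``; a window's raw score is the column sum, and
the reported score rescales the raw value to 0-100 between the minimum and
maximum attainable raw scores of the matrix.  Information content is
``sum_j (2 + sum_b p[b,j] * log2 p[b,j])`` in bits.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .annotate import Variant

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default score thresholds for calling differential affinity.
P_MAX_DEFAULT = 0.05
SCORE_MIN_DEFAULT = 80.0


@dataclass
class PFMRecord:
    """Raw position frequency matrix: per-column base counts, rows A,C,G,T."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"matrix {self.matrix_id}: counts must be 4 x L")
        if self.counts.shape[1] < 4:
            raise ValueError(f"matrix {self.matrix_id}: motif length must be >= 4")
        if np.any(self.counts < 0):
            raise ValueError(f"matrix {self.matrix_id}: negative count")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"matrix {self.matrix_id}: empty column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWMModel:
    """Log-odds scoring matrix with its raw score bounds and information content."""

    matrix_id: str
    tf_name: str
    log_odds: np.ndarray
    max_score: float
    min_score: float
    ic: float
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    def to_relative(self, raw: np.ndarray | float):
        """Rescale raw log-odds to the 0-100 relative score."""
        span = self.max_score - self.min_score
        if span == 0:
            return np.full_like(np.asarray(raw, dtype=float), 100.0) if np.ndim(raw) else 100.0
        return 100.0 * (np.asarray(raw, dtype=float) - self.min_score) / span

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.log_odds, axis=0))


def build_pwm(
    pfm: PFMRecord,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> PWMModel:
    """Convert a count matrix into a log-odds model.

    ``background`` defaults to uniform base frequencies; the pseudocount is
    distributed across bases proportionally to the background.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
        log_odds = np.log2(probs / bg[:, None])
    ic = float(np.sum(2.0 + plogp.sum(axis=0)))
    return PWMModel(
        matrix_id=pfm.matrix_id,
        tf_name=pfm.tf_name,
        log_odds=log_odds,
        max_score=float(log_odds.max(axis=0).sum()),
        min_score=float(log_odds.min(axis=0).sum()),
        ic=ic,
        background=bg,
    )


def filter_by_ic(pwms: Sequence[PWMModel], ic_min: float = 10.0) -> list[PWMModel]:
    """Retain motifs whose information content is strictly greater than ``ic_min``."""
    return [m for m in pwms if m.ic > ic_min]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0..T=3); non-ACGT bases become -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        codes[arr == b.encode()] = i
    return codes


def _window_scores(model: PWMModel, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw log-odds of every window on both strands; NaN where a window has
    a non-ACGT base.  The reverse-strand score at offset i is the score of the
    reverse complement of the same forward window."""
    L = model.length
    if codes.size < L:
        raise ValueError(f"sequence shorter than motif length {L}")
    windows = sliding_window_view(codes, L)
    invalid = (windows < 0).any(axis=1)
    safe = np.where(windows < 0, 0, windows)
    cols = np.arange(L)
    fwd = model.log_odds[safe, cols].sum(axis=1)
    lo_rc = model.log_odds[::-1, ::-1]
    rev = lo_rc[safe, cols].sum(axis=1)
    fwd[invalid] = np.nan
    rev[invalid] = np.nan
    return fwd, rev


def _best(model: PWMModel, fwd: np.ndarray, rev: np.ndarray, lo: int, hi: int):
    """Best relative score over offsets [lo, hi), ties broken by smaller
    offset then + strand.  Returns (score, offset, strand) or (nan, -1, None)
    when every window is skipped."""
    stacked = np.column_stack((fwd[lo:hi], rev[lo:hi]))
    if stacked.size == 0 or np.all(np.isnan(stacked)):
        return float("nan"), -1, None
    flat = stacked.ravel()
    best_raw = np.nanmax(flat)
    k = int(np.flatnonzero(flat == best_raw)[0])
    return float(model.to_relative(best_raw)), lo + k // 2, "+" if k % 2 == 0 else "-"


def relative_score(model: PWMModel, seq: str) -> tuple[float, int, str | None]:
    """Best 0-100 relative score over all windows of ``seq`` on both strands.

    Windows containing N are skipped; if all are skipped the score is NaN.
    """
    codes = encode_sequence(seq)
    fwd, rev = _window_scores(model, codes)
    return _best(model, fwd, rev, 0, fwd.size)


def best_scores_at(
    model: PWMModel, codes: np.ndarray, center: int
) -> float:
    """Best relative score among windows whose span contains ``center``."""
    fwd, rev = _window_scores(model, codes)
    lo = max(0, center - model.length + 1)
    hi = min(fwd.size, center + 1)
    return _best(model, fwd, rev, lo, hi)[0]


def allelic_best_scores(
    model: PWMModel,
    genome: Mapping[str, str],
    variant: Variant,
    flank: int = 30,
) -> tuple[float, float]:
    """Best SNP-overlapping relative scores for the major and minor alleles.

    The window spans ``flank`` bp on each side of the SNP (clipped to the
    chromosome); each allele is substituted at the center before scanning
    both strands.  The reference genome base must equal the major allele.
    """
    lo = max(0, variant.pos - flank)
    seq = str(genome[variant.chrom][lo : variant.pos + flank + 1]).upper()
    center = variant.pos - lo
    if center >= len(seq):
        raise ValueError(f"{variant.id}: position beyond chromosome end")
    if seq[center] != variant.major:
        raise ValueError(
            f"{variant.id}: reference base {seq[center]!r} at {variant.chrom}:"
            f"{variant.pos} does not match declared major allele {variant.major!r}"
        )
    codes = encode_sequence(seq)
    scores = []
    for allele in (variant.major, variant.minor):
        codes[center] = BASE_INDEX[allele]
        scores.append(best_scores_at(model, codes, center))
    return scores[0], scores[1]


def affinity_diff_test(diff: float, bg_diffs: np.ndarray) -> float:
    """Two-tailed empirical p-value of an allelic score difference against a
    background of matched-SNP differences, with the add-one correction."""
    bg = np.asarray(bg_diffs, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("empty background difference distribution")
    return float((1 + np.sum(np.abs(bg) >= abs(diff))) / (bg.size + 1))


def call_differential_affinity(
    score_major: float,
    score_minor: float,
    p_emp: float,
    p_max: float = P_MAX_DEFAULT,
    score_min: float = SCORE_MIN_DEFAULT,
) -> tuple[bool, str]:
    """Differential-affinity call: empirical p <= 0.05 and a score above 80
    for at least one allele.  Direction is 'increase' when the minor allele
    scores higher."""
    direction = "increase" if score_minor > score_major else "decrease"
    is_diff = p_emp <= p_max and max(score_major, score_minor) > score_min
    return is_diff, direction


@dataclass
class AffinityResult:
    """Per (SNP, PWM) allelic scores, their difference and the empirical test."""

    snp_id: str
    matrix_id: str
    tf_name: str
    score_major: float
    score_minor: float
    diff: float
    p_emp: float
    is_differential: bool
    direction: str


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def draw_matched_affinity_background(
    pool: Sequence[Variant],
    fg: Sequence[Variant],
    binning,
    n: int = 10_000,
    rng: np.random.Generator | int = 0,
) -> list[Variant]:
    """Background SNPs matched to the foreground on (substitution type,
    GC bin, TSS-distance bin), drawn without replacement.

    Strata with insufficient pool members are filled proportionally from the
    remaining capacity of other strata, with a warning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fg_ids = {v.id for v in fg}
    pool = [v for v in pool if v.id not in fg_ids]
    if n > len(pool):
        raise ValueError(f"requested {n} background SNPs from a pool of {len(pool)}")

    def stratum(v: Variant) -> tuple:
        b = binning.assign(v)
        return (v.substitution, b[1], b[2])

    fg_counts = Counter(stratum(v) for v in fg)
    groups: dict[tuple, list[int]] = {}
    for i, v in enumerate(pool):
        groups.setdefault(stratum(v), []).append(i)
    keys = sorted(fg_counts)
    weights = np.array([fg_counts[k] for k in keys], dtype=float)
    targets = _largest_remainder(weights, n)
    chosen: list[int] = []
    deficit = 0
    leftovers: dict[tuple, np.ndarray] = {}
    for key, t in zip(keys, targets):
        members = np.array(groups.get(key, []), dtype=int)
        if members.size <= t:
            chosen.extend(members.tolist())
            deficit += t - members.size
        else:
            pick = rng.choice(members, size=t, replace=False)
            chosen.extend(pick.tolist())
            leftovers[key] = np.setdiff1d(members, pick)
    if deficit:
        warnings.warn(
            f"{deficit} background draws rescaled across strata "
            "(insufficient pool members in some strata)",
            stacklevel=2,
        )
        taken = set(chosen)
        spare = np.array(
            sorted(
                {int(i) for k in leftovers for i in leftovers[k]} - taken
            ),
            dtype=int,
        )
        if spare.size < deficit:
            # relax the covariate bins but keep the substitution types
            fg_subs = {k[0] for k in keys}
            spare = np.array(
                [
                    i
                    for i, v in enumerate(pool)
                    if i not in taken and v.substitution in fg_subs
                ],
                dtype=int,
            )
        if spare.size < deficit:
            raise ValueError("pool too small for the requested background size")
        chosen.extend(rng.choice(spare, size=deficit, replace=False).tolist())
    return [pool[i] for i in sorted(chosen)]


def differential_affinity_analysis(
    snps: Sequence[Variant],
    genome: Mapping[str, str],
    pwms: Sequence[PWMModel],
    pool: Sequence[Variant],
    binning,
    n_bg: int = 10_000,
    rng: np.random.Generator | int = 0,
    flank: int = 30,
    p_max: float = P_MAX_DEFAULT,
    score_min: float = SCORE_MIN_DEFAULT,
) -> list[AffinityResult]:
    """Full differential-affinity screen of a SNP set against matched nulls.

    A single matched background set is drawn; per-PWM background difference
    distributions (minor - major, oriented by each background SNP's own
    alleles) are computed once and reused across foreground SNPs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    background = draw_matched_affinity_background(pool, snps, binning, n=n_bg, rng=rng)
    results: list[AffinityResult] = []
    for model in pwms:
        bg_diffs = np.array(
            [
                (lambda s: s[1] - s[0])(allelic_best_scores(model, genome, v, flank=flank))
                for v in background
            ]
        )
        for v in snps:
            s_maj, s_min = allelic_best_scores(model, genome, v, flank=flank)
            diff = s_min - s_maj
            p = affinity_diff_test(diff, bg_diffs)
            is_diff, direction = call_differential_affinity(
                s_maj, s_min, p, p_max=p_max, score_min=score_min
            )
            results.append(
                AffinityResult(
                    snp_id=v.id,
                    matrix_id=model.matrix_id,
                    tf_name=model.tf_name,
                    score_major=s_maj,
                    score_minor=s_min,
                    diff=diff,
                    p_emp=p,
                    is_differential=is_diff,
                    direction=direction,
                )
            )
    return results
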