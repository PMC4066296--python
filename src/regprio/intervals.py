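"""Genomic interval primitives: overlap queries, base-level set arithmetic
and replicate consensus tracks.

All coordinates are 0-based, half-open ``[start, end)``: an interval contains
its start and excludes its end.  One-based coordinates appear only at I/O
boundaries (see :mod:`regprio.io`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span, optionally carrying a nonnegative signal value."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval needs a chromosome name")
        if self.start < 0 or not self.start < self.end:
            raise ValueError(f"invalid span {self.chrom}:{self.start}-{self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.value is not None and not self.value >= 0:
            raise ValueError(f"negative signal value {self.value}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse an interval collection to its disjoint base-level coverage.

    Signal values are dropped: the result describes covered bases only.
    """
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(_by_chrom(intervals).items()):
        cur_s = cur_e = None
        for iv in ivs:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_many(interval_sets: Sequence[Iterable[GenomicInterval]]) -> list[GenomicInterval]:
    """Base-level intersection of the coverage of several interval sets."""
    sets = [merge_intervals(s) for s in interval_sets]
    if not sets:
        return []
    k = len(sets)
    events: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for iv in s:
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        cov = 0
        seg_start = 0
        # ends sort before starts at equal positions so touching spans do not
        # create spurious single-point coverage
        for pos, delta in sorted(events[chrom]):
            prev = cov
            cov += delta
            if prev < k <= cov:
                seg_start = pos
            elif prev >= k > cov and pos > seg_start:
                out.append(GenomicInterval(chrom, seg_start, pos))
    return merge_intervals(out)


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level difference: the coverage of ``a`` not covered by ``b``."""
    a_merged = merge_intervals(a)
    b_map = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in a_merged:
        s = iv.start
        for cut in b_map.get(iv.chrom, []):
            if cut.end <= s or cut.start >= iv.end:
                continue
            if cut.start > s:
                out.append(GenomicInterval(iv.chrom, s, cut.start))
            s = max(s, cut.end)
            if s >= iv.end:
                break
        if s < iv.end:
            out.append(GenomicInterval(iv.chrom, s, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


@dataclass
class FeatureTrack:
    """A named collection of intervals from one assay (or one replicate of it).

    Intervals are kept sorted by (chrom, start, end).  Point and range queries
    are served from a lazily built interval tree per chromosome; membership
    tests for many positions at once use merged coordinate arrays.
    """

    name: str
    intervals: list[GenomicInterval]
    replicate_id: str | None = None
    _trees: dict | None = field(default=None, repr=False, compare=False)
    _merged: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.intervals = sort_intervals(self.intervals)

    # -- point / range queries -------------------------------------------------
    def _tree(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees.get(chrom)

    def at(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """Intervals with start <= pos < end on ``chrom``, in coordinate order."""
        tree = self._tree(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.at(pos)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._tree(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def contains(self, chrom: str, pos: int) -> bool:
        return bool(self.at(chrom, pos))

    def value_at(self, chrom: str, pos: int, missing: float = 0.0) -> float:
        """Signal value of the covering interval; max if several cover the point."""
        vals = [iv.value for iv in self.at(chrom, pos) if iv.value is not None]
        return max(vals) if vals else missing

    # -- bulk membership -------------------------------------------------------
    def _merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._merged is None:
            merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, ivs in _by_chrom(merge_intervals(self.intervals)).items():
                merged[chrom] = (
                    np.array([iv.start for iv in ivs]),
                    np.array([iv.end for iv in ivs]),
                )
            self._merged = merged
        return self._merged

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        arrays = self._merged_arrays().get(chrom)
        pos = np.asarray(positions)
        if arrays is None:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = arrays
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = idx >= 0
        hit[hit] = pos[hit] < ends[idx[hit]]
        return hit

    def count_overlapping(self, variants) -> int:
        """Number of variants whose position falls inside the track."""
        n = 0
        by_chrom: dict[str, list[int]] = {}
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v.pos)
        for chrom, positions in by_chrom.items():
            n += int(self.contains_many(chrom, np.array(positions)).sum())
        return n


def overlap_query(track: FeatureTrack, chrom: str, pos: int) -> list[GenomicInterval]:
    """Intervals of ``track`` containing the point; empty for unknown chromosomes."""
    if pos < 0:
        raise ValueError("position must be nonnegative")
    return track.at(chrom, pos)


def _geometric_mean(values: Sequence[float]) -> float:
    if any(v == 0 for v in values):
        return 0.0
    return float(math.exp(sum(math.log(v) for v in values) / len(values)))


def replicate_consensus(replicates: Sequence[FeatureTrack]) -> FeatureTrack:
    """Consensus of replicated assays: base-level intersection of coverage,
    with the geometric mean of the covering replicate values on each piece.

    A single replicate is returned unchanged.  A zero value in any replicate
    makes the consensus value zero on that piece; value-less replicates yield
    value-less consensus pieces.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate")
    if len(reps) == 1:
        return reps[0]
    out: list[GenomicInterval] = []
    for region in intersect_many([r.intervals for r in reps]):
        breakpoints = {region.start, region.end}
        for r in reps:
            for sub in r.overlapping(region.chrom, region.start, region.end):
                for b in (sub.start, sub.end):
                    if region.start < b < region.end:
                        breakpoints.add(b)
        bps = sorted(breakpoints)
        segs: list[tuple[int, int, float | None]] = []
        for s, e in zip(bps[:-1], bps[1:]):
            vals: list[float] = []
            missing = False
            for r in reps:
                covering = [iv.value for iv in r.at(region.chrom, s) if iv.value is not None]
                if covering:
                    vals.append(max(covering))
                else:
                    missing = True
            value = None if missing else _geometric_mean(vals)
            if segs and segs[-1][1] == s and segs[-1][2] == value:
                segs[-1] = (segs[-1][0], e, value)
            else:
                segs.append((s, e, value))
        out.extend(GenomicInterval(region.chrom, s, e, value=v) for s, e, v in segs)
    return FeatureTrack(name=reps[0].name, intervals=out, replicate_id="consensus")
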