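"""Hi-C contact binning, display capping, and TAD-based target-gene inference.

Read pairs are counted into a symmetric matrix of fixed genomic bins
(20 kb by default).  For display, counts are capped at the 85th percentile
of the positive upper-triangle entries.  Candidate target genes of a SNP are
the genes whose TSS lies inside the topological domain containing the SNP.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotate import GeneModel, Variant

BIN_SIZE_DEFAULT = 20_000


@dataclass(frozen=True)
class HiCPair:
    """One mapped read pair; the two ends are unordered."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("pair positions must be nonnegative")


@dataclass(frozen=True)
class TAD:
    """A topologically associating domain, half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or not self.start < self.end:
            raise ValueError(f"invalid TAD {self.chrom}:{self.start}-{self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact counts over a window."""

    chrom: str
    start: int
    end: int
    bin_size: int
    counts: np.ndarray
    n_ignored: int = 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int) -> int:
        return (pos - self.start) // self.bin_size


def bin_hic_pairs(
    pairs: Iterable[HiCPair],
    chrom: str,
    start: int,
    end: int,
    bin_size: int = BIN_SIZE_DEFAULT,
) -> ContactMatrix:
    """Count read pairs into symmetric ``bin_size`` bins over a window.

    The window is expanded outward to bin boundaries.  Pairs that are
    inter-chromosomal, on another chromosome, or with an end outside the
    window are ignored and tallied in ``n_ignored``.  A pair with both ends
    in one bin increments the diagonal once.
    """
    start = (start // bin_size) * bin_size
    end = math.ceil(end / bin_size) * bin_size
    n = (end - start) // bin_size
    counts = np.zeros((n, n), dtype=np.int64)
    ignored = 0
    for p in pairs:
        if (
            p.chrom1 != chrom
            or p.chrom2 != chrom
            or not (start <= p.pos1 < end)
            or not (start <= p.pos2 < end)
        ):
            ignored += 1
            continue
        i = (p.pos1 - start) // bin_size
        j = (p.pos2 - start) // bin_size
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return ContactMatrix(
        chrom=chrom, start=start, end=end, bin_size=bin_size, counts=counts, n_ignored=ignored
    )


def cap_percentile(m: ContactMatrix, pct: float = 85.0) -> tuple[ContactMatrix, float]:
    """Cap counts at the ``pct``-th percentile of positive upper-triangle
    entries (display saturation).  An all-zero matrix is returned unchanged
    with cap 0."""
    iu = np.triu_indices(m.n_bins)
    upper = m.counts[iu]
    positive = upper[upper > 0]
    if positive.size == 0:
        return m, 0.0
    cap = float(np.percentile(positive, pct))
    capped = ContactMatrix(
        chrom=m.chrom,
        start=m.start,
        end=m.end,
        bin_size=m.bin_size,
        counts=np.minimum(m.counts, cap),
        n_ignored=m.n_ignored,
    )
    return capped, cap


def tad_containing(variant: Variant, tads: Sequence[TAD]) -> TAD | None:
    """The TAD whose half-open span contains the SNP; None between TADs.

    TADs from a single source must not overlap; two containing TADs is an
    error.
    """
    hits = [t for t in tads if t.chrom == variant.chrom and t.contains(variant.pos)]
    if len(hits) > 1:
        raise ValueError(f"{variant.id}: contained in {len(hits)} overlapping TADs")
    return hits[0] if hits else None


def genes_in_tad(tad: TAD, genes: Sequence[GeneModel]) -> list[str]:
    """IDs of genes whose TSS lies within the TAD, in coordinate order."""
    inside = [g for g in genes if g.chrom == tad.chrom and tad.contains(g.tss)]
    inside.sort(key=lambda g: (g.tss, g.gene_id))
    return [g.gene_id for g in inside]
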