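"""Variant and gene models, genomic covariates, functional categories and
regulatory-sequence classification.

Covariates follow the matching attributes used for background resampling:
minor allele frequency, GC fraction in a +/-500 bp window, and distance to
the nearest transcription start site on the same chromosome.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import FeatureTrack, GenomicInterval, subtract_intervals

_BASES = frozenset("ACGT")

#: Sentinel distance for variants on chromosomes without any annotated gene;
#: large enough to land in the top distance bin of any percentile binning.
NO_TSS_DISTANCE = 1 << 40

#: Functional categories from highest to lowest assignment priority.
CATEGORY_PRIORITY = ("5UTR", "3UTR", "exon", "genic", "upstream", "downstream", "intergenic")


@dataclass
class Variant:
    """A biallelic SNP with its minor allele frequency and derived covariates."""

    id: str
    chrom: str
    pos: int
    major: str
    minor: str
    maf: float
    gc500: float | None = None
    tss_dist: int | None = None

    def __post_init__(self) -> None:
        self.major = self.major.upper()
        self.minor = self.minor.upper()
        if self.major not in _BASES or self.minor not in _BASES:
            raise ValueError(f"{self.id}: alleles must be A/C/G/T")
        if self.major == self.minor:
            raise ValueError(f"{self.id}: major and minor alleles are identical")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"{self.id}: MAF {self.maf} outside (0, 0.5]")
        if self.pos < 0:
            raise ValueError(f"{self.id}: negative position")

    @property
    def substitution(self) -> str:
        """Unordered substitution type, e.g. 'AG' for an A/G polymorphism."""
        return "".join(sorted((self.major, self.minor)))


@dataclass
class GeneModel:
    """Transcript-level gene model with strand-aware TSS/TTS and exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: TSS after TTS on + strand")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: TSS before TTS on - strand")
        exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(exons[:-1], exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def body(self) -> tuple[int, int]:
        """Genomic (low, high) bounds of the gene body, both inclusive."""
        return (min(self.tss, self.tts), max(self.tss, self.tts))


def gc_content(genome: Mapping[str, str], chrom: str, pos: int, flank: int = 500) -> float:
    """GC fraction among non-N bases in ``[pos - flank, pos + flank]``.

    The window is clipped to chromosome bounds.  An all-N window yields NaN.
    """
    lo = max(0, pos - flank)
    seq = str(genome[chrom][lo : pos + flank + 1]).upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def nearest_tss_distance(variant: Variant, genes: Sequence[GeneModel]) -> int:
    """Distance in bp to the nearest TSS on the variant's chromosome.

    Chromosomes without genes return :data:`NO_TSS_DISTANCE`; an empty gene
    set is an error.
    """
    if not genes:
        raise ValueError("empty gene set")
    tss = [g.tss for g in genes if g.chrom == variant.chrom]
    if not tss:
        return NO_TSS_DISTANCE
    return min(abs(variant.pos - t) for t in tss)


def annotate_covariates(
    variants: Sequence[Variant],
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    flank: int = 500,
) -> Sequence[Variant]:
    """Fill ``gc500`` and ``tss_dist`` on each variant, in place.

    Uses per-chromosome cumulative base counts so the cost is linear in the
    genome plus the number of variants.
    """
    if not genes:
        raise ValueError("empty gene set")
    chroms = sorted({v.chrom for v in variants})
    gc_cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        seq = np.frombuffer(str(genome[chrom][:]).upper().encode(), dtype="S1")
        is_gc = (seq == b"G") | (seq == b"C")
        is_acgt = is_gc | (seq == b"A") | (seq == b"T")
        gc_cum[chrom] = (
            np.concatenate(([0], np.cumsum(is_gc))),
            np.concatenate(([0], np.cumsum(is_acgt))),
        )
        tss_by_chrom[chrom] = np.sort([g.tss for g in genes if g.chrom == chrom])
    for v in variants:
        cg, ca = gc_cum[v.chrom]
        n = len(ca) - 1
        lo = max(0, v.pos - flank)
        hi = min(n, v.pos + flank + 1)
        denom = ca[hi] - ca[lo]
        v.gc500 = float((cg[hi] - cg[lo]) / denom) if denom else float("nan")
        tss = tss_by_chrom[v.chrom]
        if tss.size == 0:
            v.tss_dist = NO_TSS_DISTANCE
        else:
            j = np.searchsorted(tss, v.pos)
            cands = tss[max(0, j - 1) : j + 1]
            v.tss_dist = int(np.min(np.abs(cands - v.pos)))
    return variants


def assign_functional_category(
    variant: Variant, genes: Sequence[GeneModel], window: int = 10_000
) -> str:
    """Highest-priority functional category containing the SNP.

    Priority: 5'UTR > 3'UTR > exon > genic (intronic gene body) > upstream
    (within ``window`` bp 5' of a TSS, strand-aware) > downstream (within
    ``window`` bp 3' of a TTS) > intergenic.
    """
    found: set[str] = set()
    pos = variant.pos
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        if any(iv.contains(pos) for iv in g.utr5):
            found.add("5UTR")
        if any(iv.contains(pos) for iv in g.utr3):
            found.add("3UTR")
        if any(iv.contains(pos) for iv in g.exons):
            found.add("exon")
        lo, hi = g.body
        if lo <= pos <= hi:
            found.add("genic")
        d_up = g.tss - pos if g.strand == "+" else pos - g.tss
        if 1 <= d_up <= window:
            found.add("upstream")
        d_down = pos - g.tts if g.strand == "+" else g.tts - pos
        if 1 <= d_down <= window:
            found.add("downstream")
    for cat in CATEGORY_PRIORITY:
        if cat in found:
            return cat
    return "intergenic"


def _intervals(x) -> list[GenomicInterval]:
    if x is None:
        return []
    if isinstance(x, FeatureTrack):
        return x.intervals
    return list(x)


def classify_regulatory_sequences(
    dnase: FeatureTrack | None = None,
    h3k4me3: FeatureTrack | None = None,
    ctcf: FeatureTrack | None = None,
    exons: Iterable[GenomicInterval] | None = None,
) -> tuple[dict[str, list[GenomicInterval]], list[str]]:
    """Classify regulatory sequence classes from consensus assay tracks.

    open_chromatin = DNase hypersensitive regions; promoter = H3K4me3;
    insulator = CTCF; pEnh (potential enhancer) = DNase coverage lacking
    H3K4me3, outside exonic bases.  Missing assays make the dependent classes
    absent; their names are returned in the second element.
    """
    classes: dict[str, list[GenomicInterval]] = {}
    missing: list[str] = []
    if dnase is not None:
        classes["open_chromatin"] = _intervals(dnase)
        classes["pEnh"] = subtract_intervals(
            subtract_intervals(_intervals(dnase), _intervals(h3k4me3)),
            _intervals(exons),
        )
    else:
        missing += ["open_chromatin", "pEnh"]
    if h3k4me3 is not None:
        classes["promoter"] = _intervals(h3k4me3)
    else:
        missing.append("promoter")
    if ctcf is not None:
        classes["insulator"] = _intervals(ctcf)
    else:
        missing.append("insulator")
    return classes, missing
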