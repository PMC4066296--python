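"""Regulatory potential index (RPI) per SNP and condition, the cancer/normal
log-ratio, TAF ChIP-seq overlap evidence, and nearby differential expression.

RPI sums, at the SNP position, the replicate-consensus signal of three
assays: DNase accessibility (RPKM), H3K4me3 and CTCF ChIP enrichment.  The
relative regulatory potential is log2((RPI_cancer + 1) / (RPI_normal + 1));
positive values favour the cancer condition.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate import Variant
from .intervals import FeatureTrack

RPI_ASSAYS = ("dnase", "h3k4me3", "ctcf")


def _assay_value(track: FeatureTrack | None, v: Variant) -> float:
    if track is None:
        return 0.0
    hits = [iv.value for iv in track.at(v.chrom, v.pos) if iv.value is not None]
    if len(hits) > 1:
        warnings.warn(
            f"{v.id}: {len(hits)} consensus intervals cover the SNP; taking the max",
            stacklevel=3,
        )
    return max(hits) if hits else 0.0


def rpi(
    v: Variant,
    dnase: FeatureTrack | None,
    h3k4me3: FeatureTrack | None,
    ctcf: FeatureTrack | None,
    chip_mode: str = "sum",
) -> float:
    """Regulatory potential index of a SNP in one condition.

    Each assay contributes the value of its consensus interval containing the
    SNP (0 where none).  ``chip_mode="sum"`` adds the three assays;
    ``chip_mode="mean"`` adds DNase to the mean of the two ChIP assays.
    """
    if chip_mode not in ("sum", "mean"):
        raise ValueError("chip_mode must be 'sum' or 'mean'")
    missing = [
        name
        for name, t in zip(RPI_ASSAYS, (dnase, h3k4me3, ctcf))
        if t is None
    ]
    if missing:
        warnings.warn(f"{v.id}: missing assay(s) {missing} contribute 0", stacklevel=2)
    d = _assay_value(dnase, v)
    h = _assay_value(h3k4me3, v)
    c = _assay_value(ctcf, v)
    return d + (h + c) / 2 if chip_mode == "mean" else d + h + c


def relative_rp(rpi_cancer: float, rpi_normal: float) -> float:
    """log2((RPI_cancer + 1) / (RPI_normal + 1)); positive favours cancer."""
    if rpi_cancer < 0 or rpi_normal < 0:
        raise ValueError("RPI values must be nonnegative")
    return math.log2((rpi_cancer + 1.0) / (rpi_normal + 1.0))


def taf_overlap_count(
    v: Variant, taf_datasets: Mapping[str, FeatureTrack]
) -> tuple[int, list[str]]:
    """Number (and sorted names) of TAF consensus datasets covering the SNP."""
    names = sorted(name for name, t in taf_datasets.items() if t.contains(v.chrom, v.pos))
    return len(names), names


def nearby_differential_expression(
    v: Variant,
    expression: pd.DataFrame,
    window: int = 200_000,
    fold: float = 2.0,
) -> list[tuple[str, float]]:
    """Genes with a TSS within ``window`` bp of the SNP whose expression
    differs by strictly more than ``fold`` between conditions.

    ``expression`` needs columns gene_id, chrom, tss, rpkm_cancer,
    rpkm_normal.  The reported effect is the signed
    log2((rpkm_cancer + 1) / (rpkm_normal + 1)).
    """
    near = expression[
        (expression["chrom"] == v.chrom)
        & ((expression["tss"] - v.pos).abs() <= window)
    ]
    out: list[tuple[str, float]] = []
    threshold = math.log2(fold)
    for row in near.itertuples(index=False):
        lfc = math.log2((row.rpkm_cancer + 1.0) / (row.rpkm_normal + 1.0))
        if abs(lfc) > threshold:
            out.append((row.gene_id, lfc))
    out.sort(key=lambda t: t[0])
    return out


@dataclass
class RPIRecord:
    """Per-SNP regulatory potential summary across the two conditions."""

    snp_id: str
    rpi_cancer: float
    rpi_normal: float
    rel_rp: float
    taf_count: int
    taf_names: list[str] = field(default_factory=list)
    de_genes: list[tuple[str, float]] = field(default_factory=list)


def build_rpi_records(
    snps: Sequence[Variant],
    cancer: Mapping[str, FeatureTrack | None],
    normal: Mapping[str, FeatureTrack | None],
    taf_datasets: Mapping[str, FeatureTrack] | None = None,
    expression: pd.DataFrame | None = None,
    chip_mode: str = "sum",
) -> list[RPIRecord]:
    """Compute RPI in both conditions plus TAF and expression annotation.

    ``cancer`` and ``normal`` map assay names ('dnase', 'h3k4me3', 'ctcf') to
    replicate-consensus tracks (None for unavailable assays).
    """
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for v in snps:
            rc = rpi(v, cancer.get("dnase"), cancer.get("h3k4me3"), cancer.get("ctcf"), chip_mode)
            rn = rpi(v, normal.get("dnase"), normal.get("h3k4me3"), normal.get("ctcf"), chip_mode)
            count, names = taf_overlap_count(v, taf_datasets or {})
            de = (
                nearby_differential_expression(v, expression)
                if expression is not None
                else []
            )
            records.append(
                RPIRecord(
                    snp_id=v.id,
                    rpi_cancer=rc,
                    rpi_normal=rn,
                    rel_rp=relative_rp(rc, rn),
                    taf_count=count,
                    taf_names=names,
                    de_genes=de,
                )
            )
    return records
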