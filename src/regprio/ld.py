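"""Linkage-disequilibrium expansion of index SNP sets from genotype dosages.

r-squared is the squared Pearson correlation of per-sample allele dosages
(composite LD), computed within a bounded genomic search distance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotate import Variant


@dataclass
class GenotypeMatrix:
    """Per-variant, per-sample allele dosage counts in {0, 1, 2}."""

    variants: list[Variant]
    samples: list[str]
    dosages: np.ndarray  # shape (n_variants, n_samples)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2}")
        self._row_by_id = {v.id: i for i, v in enumerate(self.variants)}

    def row(self, variant_id: str) -> int:
        return self._row_by_id[variant_id]


def dosage_r2(g: GenotypeMatrix, id_a: str, id_b: str) -> float:
    """Squared Pearson correlation of dosages; NaN if either SNP is monomorphic."""
    a = g.dosages[g.row(id_a)].astype(float)
    b = g.dosages[g.row(id_b)].astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_expand(
    g: GenotypeMatrix,
    index: list[Variant],
    r2_min: float = 0.80,
    max_dist: int = 500_000,
) -> list[Variant]:
    """Expand index SNPs to all SNPs in strong LD within a distance window.

    Returns the union of the index set and every genotyped SNP on the same
    chromosome within ``max_dist`` bp whose dosage r-squared with any index
    SNP is at least ``r2_min``, deduplicated by genomic coordinate.
    Monomorphic SNPs have undefined r-squared and are excluded with a warning.
    """
    for v in index:
        if v.id not in g._row_by_id:
            raise KeyError(f"index SNP {v.id} absent from the genotype matrix")
    dosages = g.dosages.astype(float)
    sd = dosages.std(axis=1)
    centered = dosages - dosages.mean(axis=1, keepdims=True)
    pos = np.array([v.pos for v in g.variants])
    chroms = np.array([v.chrom for v in g.variants])
    selected: dict[tuple[str, int], Variant] = {(v.chrom, v.pos): v for v in index}
    n_mono = 0
    n_samples = dosages.shape[1]
    for v in index:
        i = g.row(v.id)
        if sd[i] == 0:
            n_mono += 1
            continue
        cand = np.flatnonzero(
            (chroms == v.chrom) & (np.abs(pos - v.pos) <= max_dist)
        )
        cand = cand[cand != i]
        if cand.size == 0:
            continue
        mono = sd[cand] == 0
        n_mono += int(mono.sum())
        cand = cand[~mono]
        r = (centered[cand] @ centered[i]) / (n_samples * sd[cand] * sd[i])
        for j in cand[r**2 >= r2_min]:
            partner = g.variants[j]
            selected.setdefault((partner.chrom, partner.pos), partner)
    if n_mono:
        warnings.warn(
            f"{n_mono} monomorphic SNP comparison(s) skipped: r^2 undefined",
            stacklevel=2,
        )
    return sorted(selected.values(), key=lambda v: (v.chrom, v.pos))
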