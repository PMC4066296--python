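"""Readers and writers for the external formats the pipeline touches.

Conventions: coordinates are 0-based half-open inside the package; SNP and
TSS positions in tab-separated tables are 1-based (dbSNP/VCF convention) and
converted at this boundary.  BED-family files are 0-based half-open as
defined by their formats.  Readers reject malformed input rather than
silently repairing it; writers are deterministic.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, Variant
from .hic import HiCPair, TAD
from .intervals import FeatureTrack, GenomicInterval, subtract_intervals
from .ld import GenotypeMatrix
from .pwm import PFMRecord

SNP_COLUMNS = ["id", "chrom", "pos", "major", "minor", "maf"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path):
    """Open a FASTA file with an on-first-read index; sequences slice as str."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            seq = str(sequences[name][:])
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SNP tables and genotypes
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path) -> list[Variant]:
    """TSV with header id, chrom, pos (1-based), major, minor, maf."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        Variant(
            id=str(r.id),
            chrom=str(r.chrom),
            pos=int(r.pos) - 1,
            major=str(r.major),
            minor=str(r.minor),
            maf=float(r.maf),
        )
        for r in df.itertuples(index=False)
    ]


def write_snp_table(variants: Sequence[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                f"{v.id}\t{v.chrom}\t{v.pos + 1}\t{v.major}\t{v.minor}\t{v.maf:.6g}\n"
            )


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """SNP table columns followed by one integer dosage column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    samples = [c for c in df.columns if c not in SNP_COLUMNS]
    if not samples:
        raise ValueError(f"{path}: no sample dosage columns")
    variants = [
        Variant(str(r.id), str(r.chrom), int(r.pos) - 1, str(r.major), str(r.minor), float(r.maf))
        for r in df[SNP_COLUMNS].itertuples(index=False)
    ]
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        dosages=df[samples].to_numpy(dtype=np.int8),
    )


def write_genotype_table(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS + list(g.samples)) + "\n")
        for v, row in zip(g.variants, g.dosages):
            dosages = "\t".join(str(int(d)) for d in row)
            fh.write(
                f"{v.id}\t{v.chrom}\t{v.pos + 1}\t{v.major}\t{v.minor}\t{v.maf:.6g}\t{dosages}\n"
            )


# ---------------------------------------------------------------------------
# BED family
# ---------------------------------------------------------------------------

def _bed_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 intervals; the score column (if present) becomes the value."""
    out = []
    for lineno, f in _bed_lines(path):
        if len(f) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
        value = None
        strand = "."
        if len(f) >= 5 and f[4] not in (".", ""):
            value = float(f[4])
        if len(f) >= 6 and f[5] in ("+", "-"):
            strand = f[5]
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand=strand, value=value))
    return out


def read_peaks(
    path: str | Path,
    name: str | None = None,
    replicate_id: str | None = None,
    kind: str = "narrowPeak",
) -> FeatureTrack:
    """ENCODE narrowPeak (10 cols) or broadPeak (9 cols); signalValue is the
    interval value."""
    ncols = {"narrowPeak": 10, "broadPeak": 9}.get(kind)
    if ncols is None:
        raise ValueError(f"unknown peak format {kind!r}")
    intervals = []
    for lineno, f in _bed_lines(path):
        if len(f) != ncols:
            raise ValueError(f"{path}:{lineno}: expected {ncols} {kind} columns, got {len(f)}")
        signal = float(f[6])
        if signal < 0:
            raise ValueError(f"{path}:{lineno}: negative signalValue")
        strand = f[5] if f[5] in ("+", "-") else "."
        intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand=strand, value=signal))
    return FeatureTrack(
        name=name or Path(path).stem, intervals=intervals, replicate_id=replicate_id
    )


def write_peaks(track: FeatureTrack, path: str | Path, kind: str = "narrowPeak") -> None:
    extra = "\t-1\t-1\t-1" if kind == "narrowPeak" else "\t-1\t-1"
    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals):
            value = 0.0 if iv.value is None else iv.value
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}_{i}\t0\t{iv.strand}"
                f"\t{value:.6g}{extra}\n"
            )


def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12: blocks are exons; thickStart/thickEnd delimit
    the coding region, from which strand-aware UTRs are derived."""
    genes = []
    for lineno, f in _bed_lines(path):
        if len(f) != 12:
            raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns, got {len(f)}")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        gene_id, strand = f[3], f[5]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: gene records need a strand")
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ValueError(f"{path}:{lineno}: block count mismatch")
        exons = [
            GenomicInterval(chrom, start + o, start + o + s, strand=strand)
            for o, s in zip(offsets, sizes)
        ]
        if thick_start < thick_end:
            left = [
                GenomicInterval(chrom, iv.start, iv.end, strand=strand)
                for iv in subtract_intervals(
                    exons, [GenomicInterval(chrom, thick_start, end)]
                )
            ]
            right = [
                GenomicInterval(chrom, iv.start, iv.end, strand=strand)
                for iv in subtract_intervals(
                    exons, [GenomicInterval(chrom, start, thick_end)]
                )
            ]
        else:
            left = right = []
        utr5, utr3 = (left, right) if strand == "+" else (right, left)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tss=start if strand == "+" else end - 1,
                tts=end - 1 if strand == "+" else start,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def write_bed12_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, min(iv.start for iv in g.exons))):
            exons = sorted(g.exons, key=lambda iv: iv.start)
            start = exons[0].start
            end = exons[-1].end
            coding = subtract_intervals(exons, g.utr5 + g.utr3)
            if coding:
                thick_start, thick_end = coding[0].start, coding[-1].end
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(len(iv)) for iv in exons)
            offsets = ",".join(str(iv.start - start) for iv in exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t{thick_start}"
                f"\t{thick_end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def read_tads(path: str | Path) -> list[TAD]:
    return [TAD(iv.chrom, iv.start, iv.end) for iv in read_bed(path)]


def write_tads(tads: Sequence[TAD], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tads, key=lambda t: (t.chrom, t.start)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


# ---------------------------------------------------------------------------
# JASPAR-style PFM flat files
# ---------------------------------------------------------------------------

def read_pfm_collection(path: str | Path) -> list[PFMRecord]:
    """Parse the JASPAR flat dialect: '>ID NAME' headers followed by four
    count rows in A, C, G, T order, optionally bracketed and letter-prefixed."""
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    records: list[PFMRecord] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}:{i + 1}: expected '>' matrix header")
        head = line[1:].split()
        if not head:
            raise ValueError(f"{path}:{i + 1}: empty matrix header")
        matrix_id = head[0]
        tf_name = head[1] if len(head) > 1 else ""
        rows = []
        for base in "ACGT":
            i += 1
            if i >= len(lines) or not lines[i].strip():
                raise ValueError(f"matrix {matrix_id}: truncated count rows")
            tokens = lines[i].replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0].upper() in ("A", "C", "G", "T"):
                if tokens[0].upper() != base:
                    raise ValueError(
                        f"matrix {matrix_id}: rows out of A,C,G,T order "
                        f"(found {tokens[0]!r}, expected {base!r})"
                    )
                tokens = tokens[1:]
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValueError(f"matrix {matrix_id}: unparseable count row") from exc
            rows.append(row)
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(
                f"matrix {matrix_id}: row lengths differ ({sorted(len(r) for r in rows)})"
            )
        records.append(PFMRecord(matrix_id=matrix_id, tf_name=tf_name, counts=np.array(rows)))
        i += 1
    return records


def write_pfm_collection(records: Sequence[PFMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.matrix_id} {rec.tf_name}".rstrip() + "\n")
            for base, row in zip("ACGT", rec.counts):
                cells = " ".join(f"{x:g}" for x in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# Hi-C pairs and expression tables
# ---------------------------------------------------------------------------

def read_hic_pairs(path: str | Path) -> Iterator[HiCPair]:
    """Stream read pairs from a TSV with >= 4 columns
    (chrom1, pos1, chrom2, pos2; 0-based)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: fewer than 4 columns")
            try:
                yield HiCPair(f[0], int(f[1]), f[2], int(f[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed pair: {exc}") from exc


def write_hic_pairs(pairs: Iterable[HiCPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.chrom1}\t{p.pos1}\t{p.chrom2}\t{p.pos2}\n")


EXPRESSION_COLUMNS = ["gene_id", "tss_chrom", "tss_pos", "rpkm_cancer", "rpkm_normal"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression table (TSS positions 1-based on disk) as a DataFrame with
    columns gene_id, chrom, tss (0-based), rpkm_cancer, rpkm_normal."""
    df = pd.read_csv(path, sep="\t", dtype={"tss_chrom": str})
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if (df[["rpkm_cancer", "rpkm_normal"]] < 0).any().any():
        raise ValueError(f"{path}: negative RPKM")
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chrom": df["tss_chrom"],
            "tss": df["tss_pos"].astype(int) - 1,
            "rpkm_cancer": df["rpkm_cancer"].astype(float),
            "rpkm_normal": df["rpkm_normal"].astype(float),
        }
    )


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "tss_chrom": df["chrom"],
            "tss_pos": df["tss"] + 1,
            "rpkm_cancer": df["rpkm_cancer"].map("{:.6g}".format),
            "rpkm_normal": df["rpkm_normal"].map("{:.6g}".format),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Final report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "id",
    "chrom",
    "pos",
    "category",
    "rpi_cancer",
    "rpi_normal",
    "rel_rp",
    "diff_affinity_tfs",
    "taf_count",
    "nearest_gene",
    "de_genes",
]


def _fmt(x) -> str:
    if isinstance(x, float):
        return "nan" if math.isnan(x) else f"{x:.6g}"
    return str(x)


def write_report(records: Iterable[Mapping], path: str | Path) -> None:
    """One row per SNP with the prioritization evidence, in deterministic
    (chrom, pos, id) order.  ``diff_affinity_tfs`` is a sorted comma-joined
    list; ``de_genes`` joins gene:signed-log2FC items."""
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec["id"],
                "chrom": rec["chrom"],
                "pos": int(rec["pos"]) + 1,
                "category": rec.get("category", ""),
                "rpi_cancer": _fmt(rec.get("rpi_cancer", float("nan"))),
                "rpi_normal": _fmt(rec.get("rpi_normal", float("nan"))),
                "rel_rp": _fmt(rec.get("rel_rp", float("nan"))),
                "diff_affinity_tfs": ",".join(sorted(set(rec.get("diff_affinity_tfs", [])))),
                "taf_count": int(rec.get("taf_count", 0)),
                "nearest_gene": rec.get("nearest_gene", ""),
                "de_genes": ",".join(
                    f"{g}:{lfc:+.3f}" for g, lfc in rec.get("de_genes", [])
                ),
            }
        )
    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["id"]))
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in REPORT_COLUMNS) + "\n")
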