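#!/usr/bin/env python
"""Chromatin-topology context of the top candidate SNP.

Bins the Hi-C read pairs into a 20-kb contact matrix around the highest
|relative regulatory potential| SNP, caps the matrix at the 85th percentile
of its positive upper-triangle counts for display, and lists candidate
target genes: those whose TSS shares the SNP's topological domain.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from regprio import bin_hic_pairs, cap_percentile, genes_in_tad, tad_containing
from regprio import io

BASE = Path(__file__).resolve().parent.parent
SIM = BASE / "results" / "sim"
WINDOW = 1_000_000  # bp each side of the SNP


def main() -> None:
    fg = {v.id: v for v in io.read_snp_table(SIM / "foreground_snps.tsv")}
    rpi = pd.read_csv(BASE / "results" / "rpi.tsv", sep="\t")
    top_id = rpi.loc[rpi.rel_rp.abs().idxmax(), "snp_id"]
    snp = fg[top_id]
    print(f"top candidate by |relative regulatory potential|: {top_id} at "
          f"{snp.chrom}:{snp.pos + 1}")

    pairs = io.read_hic_pairs(SIM / "hic_pairs.tsv")
    matrix = bin_hic_pairs(
        pairs, snp.chrom, max(0, snp.pos - WINDOW), snp.pos + WINDOW
    )
    capped, cap = cap_percentile(matrix, pct=85)
    print(f"contact matrix: {matrix.n_bins} x {matrix.n_bins} 20-kb bins, "
          f"{matrix.counts[np.triu_indices(matrix.n_bins)].sum()} pairs binned, "
          f"display cap (85th pct of positive counts) = {cap:g}")
    mat_df = pd.DataFrame(
        capped.counts,
        index=[matrix.start + i * matrix.bin_size for i in range(matrix.n_bins)],
    )
    mat_df.to_csv(BASE / "results" / "contact_matrix.tsv", sep="\t")

    tads = io.read_tads(SIM / "tads.bed")
    genes = io.read_bed12_genes(SIM / "genes.bed12")
    tad = tad_containing(snp, tads)
    if tad is None:
        print("SNP falls between topological domains; no domain-based targets")
        targets = []
    else:
        targets = genes_in_tad(tad, genes)
        print(f"SNP domain {tad.chrom}:{tad.start}-{tad.end} contains "
              f"{len(targets)} candidate target gene(s): {', '.join(targets) or '-'}")
    pd.DataFrame({"gene_id": targets}).to_csv(
        BASE / "results" / "tad_targets.tsv", sep="\t", index=False
    )

    scratch = BASE / "scratch"
    scratch.mkdir(exist_ok=True)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(capped.counts, cmap="Reds", origin="lower")
        ax.set_title(f"Hi-C contacts around {top_id} (cap={cap:g})")
        ax.set_xlabel("20-kb bin")
        ax.set_ylabel("20-kb bin")
        fig.colorbar(im, ax=ax, label="read pairs (capped)")
        fig.savefig(scratch / "contact_heatmap.png", dpi=120)
        print(f"heatmap written to {scratch / 'contact_heatmap.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped heatmap")


if __name__ == "__main__":
    main()
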