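#!/usr/bin/env python
"""Functional categories of the foreground SNPs and their covariate-matched
enrichment in regulatory sequence classes of both conditions.

Reads the study written by 01_simulate_inputs.py, classifies regulatory
sequences (open chromatin / promoter / insulator / potential enhancer) from
the replicate-consensus tracks of each condition, and tests the foreground
against each class with 300 matched background draws.
"""
from collections import Counter
from pathlib import Path

import pandas as pd

from regprio import (
    annotate_covariates,
    assign_functional_category,
    build_binning,
    classify_regulatory_sequences,
    replicate_consensus,
    run_enrichment,
)
from regprio import io
from regprio.intervals import FeatureTrack

BASE = Path(__file__).resolve().parent.parent
SIM = BASE / "results" / "sim"
SEED = 314


def load_consensus(condition: str, assay: str) -> FeatureTrack:
    reps = [
        io.read_peaks(SIM / "tracks" / f"{condition}_{assay}_r{r}.narrowPeak",
                      name=f"{condition}_{assay}", replicate_id=f"r{r}")
        for r in (1, 2)
    ]
    return replicate_consensus(reps)


def main() -> None:
    genome = io.read_fasta(SIM / "genome.fa")
    genes = io.read_bed12_genes(SIM / "genes.bed12")
    fg = io.read_snp_table(SIM / "foreground_snps.tsv")
    pool = io.read_snp_table(SIM / "pool_snps.tsv")
    annotate_covariates(fg + pool, genome, genes)

    cats = Counter(assign_functional_category(v, genes) for v in fg)
    cat_df = pd.DataFrame(sorted(cats.items()), columns=["category", "n_snps"])
    cat_df.to_csv(BASE / "results" / "categories.tsv", sep="\t", index=False)
    noncoding = sum(n for c, n in cats.items() if c not in ("exon", "5UTR", "3UTR"))
    print(f"functional categories ({len(fg)} foreground SNPs):")
    for c, n in cat_df.itertuples(index=False):
        print(f"  {c:<11} {n}")
    print(f"  non-coding fraction: {noncoding / len(fg):.2f}")

    features = []
    exons = [iv for g in genes for iv in g.exons]
    for condition in ("cancer", "normal"):
        tracks = {a: load_consensus(condition, a) for a in ("dnase", "h3k4me3", "ctcf")}
        classes, _ = classify_regulatory_sequences(
            dnase=tracks["dnase"], h3k4me3=tracks["h3k4me3"],
            ctcf=tracks["ctcf"], exons=exons,
        )
        for cls, intervals in classes.items():
            features.append(FeatureTrack(f"{condition}_{cls}", list(intervals)))

    binning = build_binning(pool)
    results = run_enrichment(fg, pool, features, binning, n_draws=300, rng=SEED)
    df = pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "fg_count": [r.fg_count for r in results],
            "bg_mean": [r.bg_counts.mean() for r in results],
            "p_enrich": [r.p_enrich for r in results],
            "p_deplete": [r.p_deplete for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
    df.to_csv(BASE / "results" / "enrichment.tsv", sep="\t", index=False)
    print("\nenrichment of the foreground in regulatory classes:")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))


if __name__ == "__main__":
    main()
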