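#!/usr/bin/env python
"""Allelic transcription-factor binding-affinity screen of the foreground.

Scores both alleles of every foreground SNP against the motif collection in
a 61-bp window, compares each allelic score difference with a background of
matched SNPs (same substitution type, similar GC and TSS distance), and
writes the per-(SNP, motif) results with empirical p-values and calls.
"""
import warnings
from pathlib import Path

import pandas as pd

from regprio import annotate_covariates, build_binning, build_pwm, filter_by_ic
from regprio import io
from regprio.pwm import differential_affinity_analysis

BASE = Path(__file__).resolve().parent.parent
SIM = BASE / "results" / "sim"
SEED = 271


def main() -> None:
    genome = io.read_fasta(SIM / "genome.fa")
    genes = io.read_bed12_genes(SIM / "genes.bed12")
    fg = io.read_snp_table(SIM / "foreground_snps.tsv")
    pool = io.read_snp_table(SIM / "pool_snps.tsv")
    annotate_covariates(fg + pool, genome, genes)
    pfms = io.read_pfm_collection(SIM / "motifs.pfm")
    models = filter_by_ic([build_pwm(p) for p in pfms], ic_min=10.0)
    print(f"{len(models)}/{len(pfms)} motifs pass the information-content filter (> 10 bits)")

    binning = build_binning(pool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = differential_affinity_analysis(
            fg, genome, models, pool, binning, n_bg=1000, rng=SEED
        )
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "matrix_id": [r.matrix_id for r in results],
            "tf_name": [r.tf_name for r in results],
            "score_major": [round(r.score_major, 4) for r in results],
            "score_minor": [round(r.score_minor, 4) for r in results],
            "diff": [round(r.diff, 4) for r in results],
            "p_emp": [r.p_emp for r in results],
            "is_differential": [r.is_differential for r in results],
            "direction": [r.direction for r in results],
        }
    ).sort_values(["snp_id", "matrix_id"])
    df.to_csv(BASE / "results" / "affinity.tsv", sep="\t", index=False)
    calls = df[df.is_differential]
    print(f"differential-affinity calls: {len(calls)} of {len(df)} (SNP, motif) pairs")
    if len(calls):
        print(calls.to_string(index=False))


if __name__ == "__main__":
    main()
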