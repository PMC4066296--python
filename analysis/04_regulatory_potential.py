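#!/usr/bin/env python
"""Per-SNP regulatory potential index in the cancer and normal conditions.

Builds replicate-consensus tracks (base-level intersection, geometric-mean
signal) for DNase, H3K4me3 and CTCF in both conditions, sums the covering
signals into the regulatory potential index, and annotates TAF ChIP-seq
overlap counts and nearby expression changes (> 2-fold within 200 kb).
"""
from pathlib import Path

import pandas as pd

from regprio import replicate_consensus
from regprio import io
from regprio.rpi import build_rpi_records

BASE = Path(__file__).resolve().parent.parent
SIM = BASE / "results" / "sim"


def consensus(prefix: str, name: str):
    reps = [
        io.read_peaks(SIM / prefix / f"{name}_r{r}.narrowPeak", name=name,
                      replicate_id=f"r{r}")
        for r in (1, 2)
    ]
    return replicate_consensus(reps)


def main() -> None:
    fg = io.read_snp_table(SIM / "foreground_snps.tsv")
    tracks = {
        cond: {a: consensus("tracks", f"{cond}_{a}") for a in ("dnase", "h3k4me3", "ctcf")}
        for cond in ("cancer", "normal")
    }
    taf_names = sorted({p.name.rsplit("_", 1)[0] for p in (SIM / "taf").glob("*.narrowPeak")})
    tafs = {n: consensus("taf", n) for n in taf_names}
    expr = io.read_expression(SIM / "expression.tsv")

    records = build_rpi_records(fg, tracks["cancer"], tracks["normal"], tafs, expr)
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "rpi_cancer": [round(r.rpi_cancer, 4) for r in records],
            "rpi_normal": [round(r.rpi_normal, 4) for r in records],
            "rel_rp": [round(r.rel_rp, 4) for r in records],
            "taf_count": [r.taf_count for r in records],
            "taf_names": [",".join(r.taf_names) for r in records],
            "de_genes": [",".join(f"{g}:{lfc:+.3f}" for g, lfc in r.de_genes) for r in records],
        }
    )
    df.to_csv(BASE / "results" / "rpi.tsv", sep="\t", index=False)
    active = df[(df.rpi_cancer > 0) | (df.rpi_normal > 0)]
    print(f"{len(active)} of {len(df)} foreground SNPs carry regulatory signal in either condition")
    top = df.reindex(df.rel_rp.abs().sort_values(ascending=False).index).head(5)
    print("largest |relative regulatory potential|:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
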