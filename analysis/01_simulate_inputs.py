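#!/usr/bin/env python
"""Generate the synthetic study and write every input format to results/sim/.

The landscape contains one fully planted candidate SNP (cancer-only open
chromatin, motif-breaking minor allele, TAF binding in all datasets) among
500 decoy foreground SNPs, an array-style pool with LD partners, replicated
peak tracks in two conditions, TAF datasets, TAD-structured Hi-C pairs and
an expression table.
"""
from pathlib import Path

from regprio import SimulationConfig, generate_dataset
from regprio.simulate import write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 2014


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    bundle = generate_dataset(cfg)
    write_dataset(bundle, OUT)
    flagged = bundle.truth[bundle.truth.condition_specific]
    print(f"wrote synthetic study to {OUT}")
    print(f"  chromosome: {list(cfg.chrom_sizes)} ({sum(cfg.chrom_sizes.values()):,} bp)")
    print(f"  foreground SNPs: {len(bundle.fg)} (planted candidates: {len(flagged)})")
    print(f"  pool SNPs: {len(bundle.pool)}, genes: {len(bundle.genes)}")
    print(f"  LD partner pairs: {len(bundle.ld_pairs)}")
    print(f"  Hi-C pairs: {len(bundle.hic_pairs)}, TADs: {len(bundle.tads)}")
    print(f"  planted SNP id(s): {', '.join(flagged.snp_id)}")


if __name__ == "__main__":
    main()
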