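# regprio

Prioritization of candidate regulatory SNPs within GWAS risk loci.

Most trait-associated SNPs found by genome-wide association studies sit in
non-coding sequence, where their effect — if any — is usually on gene
regulation. `regprio` implements a complete pipeline for ranking such
variants by regulatory evidence, for analysts working with SNP sets,
epigenomic peak tracks, transcription-factor motif collections and Hi-C
chromatin-contact data:

1. **LD expansion** — extend index SNPs to all genotyped SNPs within 500 kb
   at dosage r² ≥ 0.80, since the causal variant need not be the typed one.
2. **Regulatory context** — classify open chromatin (DNase), promoters
   (H3K4me3), insulators (CTCF) and potential enhancers (pEnh: DNase minus
   H3K4me3, outside exons) from replicate-consensus tracks, and test whether
   the SNP set is enriched in each class against backgrounds matched on
   minor allele frequency, ±500 bp GC content and distance to the nearest
   TSS (20 percentile bins per covariate, joint matching, empirical
   p-values, Storey q-values).
3. **Allelic TF binding affinity** — scan ±30 bp around each SNP with
   position weight matrices (information content > 10 bits), score both
   alleles on the 0–100 relative log-odds scale
   `100·(s − s_min)/(s_max − s_min)`, and call a differential site when the
   allelic score difference is extreme against 10,000 substitution- and
   covariate-matched background SNPs (two-tailed empirical p ≤ 0.05) and
   either allele scores > 80.
4. **Regulatory potential index** —
   `RPI = DNase RPKM + H3K4me3 + CTCF` consensus signal at the SNP, per
   condition; the relative regulatory potential is
   `log2((RPI_cancer + 1)/(RPI_normal + 1))`.
5. **Three-criteria prioritization** — retain SNPs with |relative
   regulatory potential| and TAF (transcription-associated factor) ChIP-seq
   overlap count above the 95th percentile of all examined SNPs and at
   least one differential-affinity call; rank by TAF count, then
   |relative RP|, then best affinity p-value.
6. **Target inference** — bin Hi-C read pairs into 20-kb contact matrices
   (display-capped at the 85th percentile of positive counts) and report
   genes whose TSS shares the SNP's topological domain (TAD).

A fully parameterised synthetic-data generator (`regprio.simulate`) emulates
the statistical structure of the real inputs — array-style SNP pools with
covariates and LD partners, replicated peaks with log-normal signal in two
conditions, planted motifs whose minor allele breaks the most informative
column, TAD-structured Hi-C pairs, RPKM tables — with ground-truth labels,
so every stage is testable without downloads.

## Worked example

```python
import regprio as rp

cfg = rp.SimulationConfig(seed=0)          # one planted candidate, 500 decoys
bundle = rp.generate_dataset(cfg)
records, candidates, rpi, affinity = rp.prioritize_dataset(bundle, n_bg=500, rng=1)

top = candidates[0]
print(top.snp_id, round(top.rel_rp, 2), top.taf_count, top.affinity_calls)
```

prints

```
snp007555 5.91 8 [('SIM0001', 'decrease', 0.003992015968063872)]
```

meaning the top-ranked SNP has 2^5.91 ≈ 60-fold more regulatory signal in
the cancer condition than in normal (relative RP 5.91), overlaps all 8 TAF
ChIP-seq datasets, and its minor allele significantly weakens a binding site
of the planted motif (empirical p ≈ 0.004). This is the planted candidate
(`bundle.truth` confirms), recovered from among 500 decoy foreground SNPs.

The `analysis/` directory holds the same workflow as numbered scripts over
the on-disk formats (FASTA, BED12, narrowPeak, JASPAR-style PFM flat files,
TSV SNP/genotype/expression/Hi-C tables): `01_simulate_inputs.py` writes a
study to `results/sim/`, and `02`–`06` annotate, test enrichment, screen
affinity, compute regulatory potential, map Hi-C context and produce the
ranked candidate list plus the final per-SNP report under `results/`.

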