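# Methods

This note documents the models and procedures implemented in `regprio`, the
synthetic data they are validated on, and the numerical and design choices
made where the problem left room.

## Coordinate conventions

All coordinates are 0-based, half-open `[start, end)` inside the package; an
interval contains its start and not its end. SNP and TSS positions in TSV
tables are 1-based (dbSNP/VCF convention) and converted at the I/O boundary;
BED-family files keep their native 0-based half-open convention.

## LD expansion

Index SNPs are expanded to all genotyped SNPs on the same chromosome within
500 kb whose r² with any index SNP is at least 0.80. r² is computed as the
squared Pearson correlation of per-sample allele dosages (composite LD); a
haplotype-phase (EM) estimator would require phased data and gives the same
answer under Hardy–Weinberg equilibrium at these effect sizes. Monomorphic
SNPs have undefined r² and are excluded with a warning. The output is
deduplicated by genomic coordinate and always contains the index set.

## Covariates and matched backgrounds

Three covariates confound overlap between SNP sets and regulatory features:
minor allele frequency, GC fraction in the ±500 bp window (non-N bases), and
distance to the nearest TSS on the SNP's chromosome (SNPs on geneless
chromosomes receive a sentinel that lands in the top distance bin). Each
covariate is cut into 20 equal-probability bins at pool percentiles; values
equal to a bin edge fall into the lower bin.

Background sets for the enrichment test reproduce the foreground's **joint**
(maf, gc, tss) bin histogram — the stricter of the two readings of
"matching three attributes" — sampling without replacement within each joint
bin. A joint bin with too few pool members is relaxed to its 3×3×3 bin
neighbourhood; if that is still insufficient the draw fails loudly, naming
the bin. Pool members that happen to be foreground SNPs remain samplable
(an `exclude` option exists): forbidding the foreground's own picks makes
each bin's background rate anti-correlated with the foreground's realized
overlap, which measurably inflates both tails of the empirical test at any
pool size where bins hold few members.

Two further consequences of matching in 8,000 joint bins deserve note:

* The pool must be much larger than the number of bins. The calibration
  studies therefore use 100,000 pool SNPs (~12 per joint bin), emulating a
  genotyping-array-scale pool; with sparsely occupied bins the relaxation
  step correlates with genomic position and biases the test.
* A calibration **null** must draw the foreground with the same matcher used
  for the backgrounds (both conditioned on a common template histogram);
  foreground and background draws are then iid and exchangeable, so the
  empirical p-value is exactly uniform up to ties.

Empirical p-values use the add-one rule, `p = (1 + #{bg ≥ fg})/(N + 1)`, so
they are never zero; depletion is reported symmetrically. Across features,
p-values are corrected with Storey q-values: `π0` is estimated by the
smoother method (`π0(λ)` on λ = 0.05…0.95, cubic least-squares fit evaluated
at λ = 0.95, clamped into (0, 1]); with `π0 = 1` the procedure reduces
exactly to Benjamini–Hochberg, which the tests verify against an independent
construction.

## PWM scoring and differential affinity

Count matrices are smoothed with a pseudocount of 0.8 split by background
base frequencies (uniform by default):
`p[b,j] = (n[b,j] + 0.8·q[b]) / (N[j] + 0.8)`; log-odds are `log2(p/q)`.
Information content is `Σ_j (2 + Σ_b p log2 p)` bits, and only motifs with
IC strictly greater than 10 bits enter the screen. A window's raw score is
the log-odds column sum; reported scores are rescaled to 0–100 between the
matrix's minimum and maximum attainable raw scores. Scanning covers both
strands (the reverse-strand score of a window is the score of its reverse
complement); windows containing non-ACGT bases are skipped, and ties are
broken by smaller offset, then + strand.

For a SNP, both alleles are substituted at the center of the ±30 bp window
and the best score among SNP-overlapping windows is retained per allele.
The reference genome base must equal the declared major allele; mismatches
are hard errors rather than silent swaps. The allelic difference
(minor − major) is compared two-tailed against the differences of background
SNPs matched on unordered substitution type and the same GC/TSS bin scheme
(10,000 by default; strata short of pool members are refilled from the
remaining capacity, keeping substitution types, with a warning). A SNP–TF
pair is called differential when the empirical p ≤ 0.05 **and** either
allele scores > 80 — the score floor separates affinity changes at
plausible sites from changes in the noise.

## Regulatory potential and expression context

Replicated tracks are consolidated by base-level intersection, with the
geometric mean of covering replicate values on each intersected piece (a
zero value in any replicate makes the consensus zero; values must be
positive for the mean to be informative). The regulatory potential index of
a SNP in one condition sums the covering consensus values of DNase (RPKM),
H3K4me3 and CTCF; each assay contributes 0 where no interval covers the SNP,
and a missing assay contributes 0 with a warning. The alternative reading
that averages the two ChIP assays before adding DNase is available as
`chip_mode="mean"`. The relative regulatory potential is
`log2((RPI_cancer + 1)/(RPI_normal + 1))` — antisymmetric, zero when the
conditions agree, positive when the cancer condition carries more signal.

Genes with a TSS within ±200 kb of a SNP are reported as differentially
expressed when `|log2((RPKM_cancer + 1)/(RPKM_normal + 1))| > log2(2)`,
strictly — an exactly 2-fold change is excluded.

## Three-criteria prioritization

A candidate must satisfy all of: |relative RP| ≥ threshold; at least one
differential-affinity call; TAF ChIP-seq overlap count ≥ threshold. Both
thresholds default to the 95th percentile of the examined SNPs (the TAF
percentile rounded up to an integer) and can be overridden; comparisons are
inclusive, so degenerate distributions still admit candidates. Ranking is by
TAF count (desc), |relative RP| (desc), best affinity p (asc), then SNP id,
which makes the order a deterministic total order.

## Hi-C and target inference

Intra-chromosomal read pairs with both ends in the analysis window are
counted into symmetric 20-kb bins (the window is expanded outward to bin
boundaries; a pair with both ends in one bin increments the diagonal once;
everything else is tallied as ignored). For display, counts are capped at
the 85th percentile of the **positive upper-triangle** entries of the
plotted window — zeros are excluded so that sparse matrices do not drag the
cap to 0. No normalization (ICE/KR) is applied and TADs are inputs, not
called. Candidate targets of a SNP are the genes whose TSS lies in the
SNP's half-open TAD span; overlapping TADs within one source are an error.

## Synthetic data

The generator produces i.i.d. genomes at 41% GC with uniformly placed genes
(3–6 exons, strand-aware UTRs), an array-style SNP pool (MAF uniform on
[0.05, 0.5], Hardy–Weinberg dosages for 120 samples), designated LD partner
pairs built by copying the anchor's dosage vector with 2% flip noise
(resampled, then copied exactly, if a small cohort leaves the realized
r² below 0.85), replicated peak tracks per condition with ±10 bp replicate
jitter and log-normal signal, TAF datasets, a TAD tiling with
within/between pair rates λ_in : λ_out, and an RPKM table with planted
fold changes.

The planted motif (`SIM0001`) is a 12-column matrix of realistic strength —
four sharp columns (95% consensus base), one deterministic core column and
seven weak columns — giving ~11 bits of information, a 0–100 score span in
which breaking the core column costs ~18 points, and a planted/null score
difference separation that leaves planted disruptions recoverable at the
study sizes below. Planting writes the consensus into the genome with the
core column on the SNP, sets the major allele to the consensus base and the
minor to the worst base there; a second pass re-asserts each planted SNP's
base where two planted copies overlap, and other variants' declared majors
are re-synchronised with the edited genome.

Default study conditions (one `SimulationConfig`): a 2 Mb chromosome, 60
genes, 10,000 pool SNPs, a foreground of 501 SNPs of which exactly one is a
fully planted candidate — cancer-only DNase peak (log-signal 3.6, i.e. RPI
≈ 37 and relative RP ≈ 5.2), no H3K4me3 (so the site classifies as a
potential enhancer), planted peaks in all 8 TAF datasets, and the
motif-breaking allele. Decoys see only background peaks (50/20/25 DNase/
H3K4me3/CTCF peaks per Mb per condition).

What the generator does **not** emulate: realistic LD beyond designated
pairs, mutation-spectrum or GC-biased SNP placement, chromatin-state
autocorrelation along the genome, distance decay within Hi-C domains, or
any coupling between motif occurrences and open chromatin. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under controlled structure, not performance on real epigenomes.

## Validation studies and problem sizes

The acceptance checks (also recomputed by `scripts/acceptance.py`) run at
sizes chosen to keep the full suite in a few minutes on one CPU:

* interval overlap and PWM scanning against brute-force oracles (1,000
  points × 500 intervals; 100 random 200-bp sequences × 5 random motifs,
  agreement to 1e-9);
* enrichment type-I error: 200 matcher-drawn null foregrounds of 200 SNPs,
  200 matched draws each, against a feature covering 20% of a 100,000-SNP
  pool on a 20 Mb chromosome — the p ≤ 0.05 rate must lie in [0.03, 0.07];
* enrichment power: foregrounds with 30% of SNPs in a feature covering 5%
  of the pool, detected at p ≤ 0.05 in ≥ 90% of 100 runs;
* affinity recovery: ≥ 95% of 200 planted motif-breaking SNPs called
  differential against 2,000 matched backgrounds on a 4 Mb chromosome with
  a 20,000-SNP pool, with matched null SNPs reaching p ≤ 0.05 at ~5%;
* Hi-C conservation and symmetry after 100,000 insertions, exactly;
* the q-value/BH identity at π0 = 1 to 1e-12 on 1,000 p-values;
* end-to-end: the planted candidate retained and ranked first in ≥ 90% of
  50 studies at the default conditions (500 affinity backgrounds per study).

## Known limitations

* Joint-bin matching needs array-scale pools; with small pools the
  neighbourhood relaxation correlates with genomic position and the
  enrichment test loses calibration (this is measured, not hypothetical —
  see the calibration discussion above).
* The affinity background refill under stratum shortage trades exact
  covariate matching for substitution-type fidelity.
* Geometric-mean consensus values require positive signals; a zero silences
  the consensus piece.
* `nearest_tss_distance` is chromosome-restricted by design; cross-
  chromosome TSS distances are never used.
* The percentile display cap and the TAD-membership target rule are
  presentation/inference conventions, not statistical procedures.
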