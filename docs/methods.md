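# Methods

This note documents the models, procedures, parameter choices and known
limitations of `dielscan`, in the order the pipeline runs them.

## Coordinate and data conventions

All genomic coordinates are 0-based, half-open (BED convention); the TSS
of a minus-strand gene is its larger coordinate. Expression travels as a
long table `(gene_id, genotype_id, replicate, time_h, count, norm_value)`.
Normalized abundance is raw count divided by a median-of-ratios size
factor computed per genotype across that genotype's samples, mirroring a
study design in which every inbred is quantified against its own genome
assembly. Missing timepoints are permitted everywhere; every statistic
operates on the observed `(t, y)` pairs.

## Cosinor model and rhythmicity test

One series is modelled as `y(t) = M + A·sin(ωt + φ) + ε` with
`ω = 2π/24 h` and i.i.d. Gaussian errors. The period is fixed at 24 h: a
single-cycle diel design carries almost no information to estimate period,
and the scientific question is diel rhythmicity, not period estimation.
Substituting `a = A cos φ, b = A sin φ` makes the model linear; OLS on
`[1, sin ωt, cos ωt]` is the exact MLE. Amplitude and phase follow as
`A = √(a²+b²)`, `φ = atan2(b, a)`, peak time `= ((π/2 − φ)/ω) mod 24`.

The rhythmicity test is the likelihood ratio against the intercept-only
model, `LR = n·ln(RSS₀/RSS₁)`, df 2. **P-values use the exact
finite-sample null distribution**, exploiting that under the Gaussian null
the LR is a strictly increasing function of
`F = ((RSS₀−RSS₁)/2)/(RSS₁/(n−3)) ~ F(2, n−3)`. At the 12-point field
grid the χ²(2) approximation has true size ≈ 0.032 at nominal 0.01
(computable in closed form from the F tail), which would make any claim of
calibrated gene counts meaningless; the F mapping is exact at every n.
The test-suite calibration check (10,000 null simulations) holds the
rejection rate at α = 0.01 to within ±0.004.

Degenerate inputs: a constant series has `RSS₀ = 0` and is reported as
`LR = 0, p = 1, R² = 0`; a perfect sinusoidal fit (`RSS₁ = 0`) is reported
as `p = 0` with a `perfect_fit` flag. Fitting requires ≥ 4 observations
and ≥ 3 distinct timepoints.

`CosinorModel(times, values).fit()` returns a results object with
estimates, delta-method standard errors (using the unbiased residual
variance), the LR test, `summary()` and `plot()`.

## Amplitude-difference test between groups

The growth-chamber confirmation compares two groups of series (haplotype
groups; replicates and genotypes within a group pooled as independent
observations). Full model: per-group `(M, A, φ)` — six parameters, fitted
by per-group OLS. Reduced model: shared `A`, per-group `(M, φ)` — five
parameters — fitted by profiling the pooled RSS over the common amplitude:
for fixed `A` each group's RSS is minimized over `(M, φ)` with `M` profiled
analytically and `φ` found on a 360-point grid polished by bounded scalar
minimization; the outer minimization over `A` uses a coarse grid plus
bounded refinement. `LR = n·ln(RSS_red/RSS_full)`, df 1, with the p-value
again from the finite-sample F mapping (`F(1, n−6)`).

Pooling genotypes within a haplotype group assumes a **common baseline**;
the synthetic generator draws the MESOR per pan-gene (shared across
inbreds, with optional per-genotype log-normal jitter
`mesor_genotype_cv`, default 0) precisely so that this assumption holds in
simulation and the test's power and calibration can be measured cleanly.
On real data, between-genotype baseline differences inflate the residual
variance of pooled groups and reduce power — a property of the pooled
test itself, not of this implementation.

## DDR detection (field design)

Response per inbred: diel range = max − min of the replicate-averaged
abundance over the course — invariant to baseline differences between
inbreds. Groups: promoter haplotype IDs; singleton haplotype groups are
retained (the rank test tolerates them, and no exclusion rule is part of
the procedure). The Kruskal–Wallis H (tie-corrected; scipy's
implementation for the observed value) is compared against a
label-permutation null: 10,000 seeded permutations with the
`(1 + #{H* ≥ H})/(1 + n_perm)` estimator, or exact enumeration of all
distinct label assignments when there are ≤ 200 of them (plain proportion,
observed assignment included). The permutation p-value can therefore never
be zero, and exhaustive mode makes small configurations exactly testable.

Candidacy thresholds: permutation p < 0.05, ≥ 6 inbreds cycling at
p < 0.01, ≥ 6 inbreds with baseline abundance > 50. "Baseline" is
defined here as the mean normalized abundance across the course (the
procedure needs a level summary; mean is robust and simple — median or
minimum can be supplied instead).

## Synthetic study generator

The generator emulates the two sampling designs: a **field** design — 24
inbreds, one series per inbred, hours 6, 8, …, 28 (12 samples, 6 am to
4 am) — and a **growth-chamber** design — 3 genotypes (configurable to 4),
hours 0, 3, …, 30 (11 samples), 2 replicates. Expression follows the
cosinor model exactly: additive Gaussian noise (σ = 0.3 by default) on the
normalized scale, clipped at zero; the written `count` column is a rounded
rendering under per-sample log-normal library factors, while `norm_value`
carries the exact model draw so that the generator's distribution matches
the tests' likelihood and calibration properties are exact.

Per pan-gene: presence in all inbreds with probability `core_fraction`
(0.85), otherwise a random subset; 1–4 promoter haplotypes assigned at
random (exactly 2 for DDR genes, with amplitudes 0 and 3 by default);
phase uniform on [0, 2π), shared across a gene's inbreds; MESOR log-normal
(median 200) per pan-gene. DDR genes are drawn among core genes so both
haplotype classes are well populated.

Default composition: 180 pan-genes with 15% DDR and 10% ordinarily
rhythmic (shared amplitude 1.5–3). This is deliberately **DDR-enriched**
relative to a real transcriptome, where ordinary cycling genes outnumber
DDR genes many-fold. The reason is statistical: every rhythmic non-DDR
gene passes the cycling and abundance filters and reaches the KW test,
whose null rejection rate at α = 0.05 is exactly 5%, so the false
discovery proportion of the field screen is governed by the base-rate
ratio of rhythmic to DDR genes. The default composition makes the
candidate set dominated by true effects so that recovery (sensitivity and
FDP) measures the machinery rather than the base rate. At realistic base
rates the field screen's FDP would be far higher — which is exactly why
the procedure includes the independent chamber confirmation stage.

Promoters: 1500 bp per (pan-gene, haplotype), i.i.d. background at the
configured GC; rhythmic alleles receive 1–3 non-overlapping copies of the
planted motif (Evening Element `AAATATCT`) at uniform positions, recorded
in the truth ledger. SNPs: uniform positions on the synthetic chromosome;
GWAS p-values Uniform(0,1) except within ±1 kb of DDR genes, where they
are drawn from Beta(0.1, 1); genotypes in Hardy–Weinberg proportions at
MAF ~ Uniform(0.05, 0.5); the adaptation SNP set takes spiked SNPs with
probability 0.5 plus background SNPs at rate 0.01.

What the generator does **not** emulate: linkage disequilibrium,
count-overdispersion, between-genotype baseline variation (optional,
default off), non-sinusoidal waveforms, and trans-acting variation.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions, not performance on real transcriptomes.

## Enrichment tests

Gene windows are the gene span ± 1 kb (half-open). The GWAS statistic is
the mean over genes of the minimum association p-value in the window;
genes whose window holds no scored SNP are dropped from the mean and
counted. Null gene sets: all genes; transcribed genes (maximum normalized
abundance above a floor); genes cycling in ≥ 2 inbreds; genes cycling in
≥ 22 inbreds. Candidates are not excluded from null sets (inclusion is the
conservative choice). Sampling is without replacement, 1,000 samples;
when the number of distinct samples is ≤ 5,000 the null is enumerated
exhaustively and the p-value is the plain proportion. In every
Monte-Carlo test ties count as extreme and the +1/+1 estimator is used,
for both directions; this keeps p-values in (0, 1] and makes "no signal
anywhere" return p ≈ 1 rather than a spurious floor value.

Weir–Cockerham Fst (two populations, diploid) is computed per site from
the a/b/c variance components; sites with `a+b+c = 0` (monomorphic) are
missing. The top-10,000 selection breaks ties at the cutoff by genomic
order. Fisher's combined statistic is `−2Σln p ~ χ²(2k)`.

The night−day response is `night − day` per (gene, individual); cis-eQTL
are simple linear regressions of the response on additive dosage for SNPs
within ±5 kb of the gene span (missing genotypes dropped pairwise,
monomorphic SNPs skipped, ≥ 10 individuals required). The matched overlap
test bins all SNPs by MAF decile × distance-to-nearest-gene bin
({0}, (0,500], (500,1000], (1000,2500], (2500,5000], >5000 bp) and, per
draw, samples for every cis-eQTL SNP one *other* SNP from its stratum
(widening to neighboring MAF bins with a warning if a stratum has no
partner); the statistic is the count of GWAS hits (p < 1e-5) among the
drawn SNPs.

## Promoter sequence model

Architecture (desk scale): 32 convolutional filters of width 13 over
one-hot DNA (valid mode; `N` encodes as 0.25 in all four rows), an
**exponential** first-layer activation, max-pooling of width 6, a
bidirectional LSTM with 16 units per direction over the pooled positions,
a position-invariant readout (concatenated max and mean over time of the
BiLSTM output) and a dense head (32 ReLU units) regressing three labels:
relative amplitude, −log₁₀ p capped at 20 (raw p is bounded and heavily
skewed; the cap keeps perfect fits finite), and R². Labels are
standardized on the training split so the summed MSE loss weights the
three outputs comparably; predictions are returned on the original scale.

Choices worth recording: the exponential first-layer activation is used
because its curvature concentrates gradient on the strongest sequence
matches, which empirically drives individual filters to represent whole
motifs rather than distributing a motif across many partial filters — at
desk scale this is the difference between recoverable and unrecoverable
filter motifs. The max+mean temporal readout keeps the head
position-invariant, which matters when motifs occur at arbitrary promoter
positions and the training set is small. Training: Adam (lr 7e-3), batch
32, 20 epochs, full determinism under the configuration seed
(single-threaded float64 numpy; the network and its reverse-mode autodiff
live in `dielscan.nn` and are finite-difference checked in the tests).
The train/validation split is by genotype (desk default 3/1) so no
pan-gene's allele from a validation genotype leaks into training under a
shared haplotype sequence.

Filter-to-motif conversion scans all sequences, collects the filter-width
subsequences wherever a filter activates at ≥ 0.5 of its global maximum,
and stacks them into a position frequency matrix with pseudocount 1;
filters with < 10 activating sites are dropped. Motif similarity is the
maximum over ungapped alignments (≥ 5 overlapping columns) and both
strands of the mean per-column Pearson correlation; zero-variance columns
contribute 0. IUPAC references expand to uniform distributions over their
allowed bases.

The desk-scale benchmark trains on ~450 promoter alleles from 4 synthetic
genotypes (100 pan-genes, half rhythmic). It demonstrates planted-motif
recovery and genotype-held-out predictive signal; it says nothing about
genome-scale predictive accuracy on real promoters.

## Problem sizes and runtime

All simulation-based checks are sized for a single CPU: 10,000 null
series for LR calibration, the 180-gene default study with 10,000 KW
permutations for DDR recovery, 200 repetitions for each enrichment
calibration, and five training seeds for motif recovery. The full test
suite and the acceptance script each run in minutes.
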