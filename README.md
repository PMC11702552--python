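# dielscan

Tools for studying **natural allelic variation in diel (24 h) transcription**
in a diversity panel of inbred lines — the setting where the same gene,
observed in many genomes, cycles in some of them and not in others, and
where the difference co-segregates with promoter sequence.

The package implements the full analysis chain as a tested library plus a
small CLI, and ships a synthetic-data generator with a complete ground-truth
ledger so every stage can be exercised and scored without any external data.

## What it computes

**Rhythmicity (cosinor likelihood-ratio test).** Expression of one gene in
one genotype over a diel time course is modelled as

```
y(t) = M + A·sin(2πt/T + φ) + ε,   ε ~ N(0, σ²),  T = 24 h
```

with MESOR `M`, amplitude `A` and phase `φ` (reported as peak time in
hours). Writing `a = A·cos φ`, `b = A·sin φ` the model is linear and the MLE
is ordinary least squares on `[1, sin ωt, cos ωt]`. Rhythmicity is tested
by the likelihood ratio against the intercept-only model,
`LR = n·ln(RSS₀/RSS₁)`, with p-values from the exact finite-sample null
distribution (the LR is a monotone function of the classical `F(2, n−3)`
statistic, and the χ² approximation is badly anticonservative at 12
timepoints). The relative amplitude is `A/M`.

**Differential Diel Regulation (DDR).** For each pan-gene (a homology group
across the panel's genome assemblies), the per-inbred diel range
(max − min abundance over the course) is tested against promoter-haplotype
grouping with a Kruskal–Wallis statistic and a 10,000-label-permutation
null (exact enumeration on small configurations). A pan-gene is a DDR
candidate when the permutation p < 0.05, at least six inbreds cycle
(p < 0.01), and at least six inbreds have baseline abundance > 50.
Candidates are confirmed in an independent growth-chamber design by
amplitude-difference LR tests between haplotype groups (minimum p over
pairwise tests when three haplotypes are present; α = 0.01).

**Enrichment.** Candidate gene sets are tested for GWAS signal (mean of the
minimum association p-value per gene ± 1 kb, against 1,000 equal-size
samples from four null gene sets) and for overlap with adaptation-candidate
SNPs (same sampling, higher-is-enriched). Per-site Weir–Cockerham Fst
between phenotype-extreme groups supplies adaptation candidates (top 10,000
sites); p-values across selection scans combine by Fisher's method.

**Night−day eQTL.** The night − day abundance difference is scanned for
cis-eQTL within 5 kb of the focal gene (additive-dosage regression); the
overlap of cis-eQTL with GWAS hits (p < 1e-5) is compared against 10,000
random SNP draws matched for MAF decile and distance to the nearest gene.

**Promoter model.** A DanQ-family network (convolution over one-hot DNA →
max-pool → bidirectional LSTM → dense head) regresses three
rhythmicity labels — relative amplitude, −log₁₀ p (capped), R² — from the
−1000/+500 bp promoter window, implemented on a small numpy reverse-mode
autodiff engine (`dielscan.nn`). Trained first-layer filters are converted
to sequence motifs by activation alignment and scored against references
(e.g. the Evening Element `AAATATCT`) by best mean per-column Pearson
correlation over ungapped alignments of both strands.

## Worked example

```python
import numpy as np
from dielscan import CosinorModel

t = np.arange(6, 30, 2.0)                      # field design: 6am .. 4am
rng = np.random.default_rng(0)
y = 200 + 3 * np.sin(2 * np.pi * t / 24 + 1.0) + rng.normal(0, 0.3, 12)
print(CosinorModel(t, y).fit().summary())
```

```
Cosinor model results
==============================================
n observations                              12
period (h)                               24.00
R-squared                               0.9916
LR statistic (df 2)                    57.3834
p-value                              4.514e-10
----------------------------------------------
                     estimate        std err
mesor                200.0066         0.0619
amplitude              2.8586         0.0876
phase_rad              1.0049         0.0306
peak_time_h            2.1618         0.1170
rel. amplitude         0.0143
==============================================
```

The fit recovers the planted parameters — amplitude 3, MESOR 200, phase
1.0 rad (true peak time (π/2 − 1)/ω ≈ 2.16 h) — and rejects the
constant-mean model decisively. A full synthetic study —
pan-genes, haplotypes, field and chamber courses, promoters with planted
motifs, SNPs with spiked GWAS p-values, plus `truth.json` — comes from:

```bash
dielscan simulate --seed 1 --outdir study/
dielscan rhythm --expr study/field_expr.tsv --out study/rhythm.tsv
dielscan ddr --expr study/field_expr.tsv --haplotypes study/haplotypes.tsv \
             --rhythm study/rhythm.tsv --seed 1 --out study/ddr.tsv
```

The DDR subcommand reports, e.g., `29 DDR candidates of 180 pan-genes`,
which can be compared against the DDR flags recorded in `study/truth.json`.

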