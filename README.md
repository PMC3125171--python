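# matreg — mating-type target-gene transcriptomics

`matreg` reimplements, as a tested and reusable pipeline, the genome-wide
identification and regulatory classification of mating-type
transcription-factor target genes in the heterothallic fungus *Podospora
anserina*. The two mating types are determined by dissimilar idiomorphs:
*mat+* carries the MATA_HMG regulator **FPR1**, *mat−* carries the MATα_HMG
regulator **FMR1** (plus *SMR1*/*SMR2*, silent in vegetative mycelium).
Comparing the transcriptomes of *mat+*, *mat−*, *fpr1−* and *fmr1−* strains
— each hybridised against a common reference on two-color microarrays —
lets one attribute every mating-type-correlated expression difference to
FPR1, FMR1, mating-type-linked SNPs, or combinations thereof.

The package is aimed at anyone who wants to re-run, audit or extend this
kind of factorial wild-type/mutant regulon analysis, on real tables or on
synthetic data with planted ground truth.

## What is implemented

* **Synthetic data** (`matreg.simulate`) — probe-level two-color intensities
  for the 4-genotype × 4-replicate design with planted FPR1/FMR1/SNP
  effects, per-gene variances drawn from a scaled inverse-chi-square prior
  (`σ²_g ~ s₀² d₀ / χ²_{d₀}`), non-expressed genes, quality flags; Cq tables
  with stable reference genes; ortholog sets with planted overlap.
* **Differential transcription** (`matreg.microarray`) — flag filtering,
  local background subtraction, within-array loess normalisation of
  M = log₂(sample/ref) on A = ½·log₂(sample·ref), probe-median aggregation,
  and an empirical-Bayes moderated t on the indirect genotype contrasts:

      s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),
      t_g  = (m̄₁ − m̄₂) / (s̃_g √(1/n₁ + 1/n₂)),  df = d₀ + d_g,

  with Benjamini–Hochberg adjustment and the selection rule |FC| ≥ 2,
  adjusted p < 0.005 (FC is the signed fold change: r if r ≥ 1, −1/r
  otherwise).
* **Regulatory classification** (`matreg.classify`) — per-factor A/R/0
  calls from the diagnostic comparisons (FPR1 ← *mat+ vs fpr1−*,
  FMR1 ← *mat− vs fmr1−*, SNP ← *fpr1− vs fmr1−*), the nine-class
  partition, the borderline (1.8 ≤ |FC| < 2) and composite
  (|FC₁|·|FC₂| ≈ |FC(mat+ vs mat−)|) class-8 rescue annotations, and
  mating-type-specific expression via the signal-to-standard-deviation
  ratio (expressed ⇔ SSR > 3).
* **RT-qPCR methods** (`matreg.qpcr`) — dilution-series efficiencies
  (E = 10^(−1/slope)), geNorm stability M and pairwise variation V with the
  V < 0.15 / MIQE ≥ 3 reference-selection rules, and REST-style
  efficiency-corrected expression ratios with a fixed-reallocation
  randomisation test and bootstrap interval.
* **Interspecies statistics** (`matreg.interspecies`) — Yates-corrected
  chi-square on the 2×2 ortholog-overlap contingency table and
  Pearson/Spearman/Kendall correlation of signed-log fold changes.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate.py` … `05_interspecies_overlap.py`).
Selected output:

```
simulated 1000 genes x 16 arrays (64000 spots), seed 1
planted classes: {'1': 1, '2': 1, '3': 1, '4': 17, '5': 9, '6': 1, '8': 4, '9': 1}
empirical-Bayes variance prior: d0 = 1.77, s0 = 0.155 (planted: d0 = 4, s0 = 0.15 ...)
per-class gene counts: {"1": 0, "2": 0, "3": 2, "4": 17, "5": 9, "6": 1, "7": 0, "8": 5, "9": 1, "unassigned": 965}
mating-type-specific calls: 13 mat+ (planted 13), 8 mat- (planted 6)
planted-class recovery: 99.8% of 1000 genes
class-8 composite rescues: 3
MAT1-2-1 vs FPR1: 29 orthologous pairs, chi2 = 45.8, p < 0.0001
```

Reading: with |log₂ effect| = 1.5 and residual scale s₀ = 0.15 at n = 4
replicates, the pipeline recovers 99.8 % of planted class labels; the
specificity caller finds the 13 planted *mat+*-specific genes exactly and
over-calls *mat−* by two genes sitting at the detection threshold; the
published cross-species overlap counts are all highly significant. The
class-8 rescue demonstrates the composite rule: a gene activated 1.69-fold
by FPR1 and repressed 1.75-fold by FMR1 combines to a predicted
1.69 × 1.75 = 2.96-fold *mat+ vs mat−* difference.

A `matreg` CLI mirrors the stages (`simulate`, `de`, `classify`, `qpcr`,
`overlap`, `run-all`); see `matreg --help`.

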