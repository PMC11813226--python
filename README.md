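# crossnet

Multi-tissue transcriptome analysis for intervention studies: differential
expression, direction-aware treatment-reversal accounting, tissue-specific
co-expression modules with cross-tissue eigengene correlation, gene-set
enrichment, and expression-constrained metabolic reaction-activity scoring.

## Who this is for

The package re-implements, as a tested and reusable pipeline, the analysis
pattern of a four-arm dietary intervention profiled by bulk RNA-seq in
several tissues of the same animals — a control group, a challenge group
(e.g. sucrose-sweetened water), and two treatment doses on top of the
challenge — where the questions are: which genes does the challenge
perturb, which of those does the treatment push back, do tissues agree,
which co-expression modules carry the response and talk to each other
across tissues, and how does predicted metabolic reaction activity shift?
A bundled synthetic-study generator with planted ground truth lets every
stage be exercised and validated end-to-end without any download.

## The statistics at the core

- **Differential expression.** Median-of-ratios size factors
  `s_j = median_g( x_gj / (prod_k x_gk)^(1/n) )`, per-gene NB dispersion by
  pooled within-group method of moments `phi = (s² − m̄)/m̄²` (floored), and
  a Wald test on `log2FC = log2(m₁/m₂)` with delta-method standard error
  `SE² = (1/m₁ + phi)/n₁ + (1/m₂ + phi)/n₂`, t reference with `n₁+n₂−2` df,
  BH adjustment; DEGs at `padj < 0.01`. A deliberately small stand-in for
  DESeq2 (no shrinkage, no Cook's/independent filtering) whose null
  calibration is verified by simulation.
- **Reversal accounting.** Suppressed = challenge-up ∩ treatment-down;
  restored = challenge-down ∩ treatment-up; percentages of the challenge
  sets; upper-tail hypergeometric overlap p computed in log space; Jaccard
  similarity; cross-tissue Spearman concordance of shared DEG log2FCs.
- **Co-expression modules.** Mean-TPM ≥ 1 filter, all-pairs Spearman rho
  with BH across pairs, positive edges at FDR < 0.05 cut to the top decile,
  Leiden modularity communities (modules ≥ 30 genes, labelled `Tissue.M0`
  by descending size), module eigengene = PC1 of the gene-standardized
  module submatrix, hypergeometric module–DEG enrichment, and BH-controlled
  Spearman correlation of inter-tissue eigengenes matched by animal.
- **Metabolic activity.** On a stoichiometric model with GPR rules
  (AND → min, OR → sum), each reaction's score is `−log` of the minimal
  expression-derived penalty `Σ pen_i |v_i|`, `pen_i = 1/(1+expr_i)`,
  achievable while holding the reaction at ≥ 95% of its maximal
  steady-state flux (two LPs per reaction and sample). Differential
  activity per contrast by Wilcoxon rank-sum + BH with Cohen's d and
  subsystem summaries.

## Worked example

```sh
python examples/03_reversal_accounting.py
```

prints

```
sucrose-induced genes suppressed by dose 1: 123/202 (60.9%), hypergeometric p = 6.83e-133
sucrose-repressed genes restored by dose 1: 46/86 (53.5%)
overall reversal fraction: 0.587 (planted: 0.6)
```

A study with 60% of challenge DEGs planted as reversed under dose 1 is
simulated; the DE stage calls DEGs for the challenge and treatment
contrasts, and the reversal statistic recovers the planted fraction
(0.587 vs 0.6) with an overlap far beyond chance (hypergeometric
p ≈ 7e-133 against the 2000-gene universe). The other scripts in
`examples/` demonstrate simulation, DE, module detection with a planted
cross-tissue coupling, GMT enrichment, reaction scoring, and the full
pipeline; `crossnet run --seed 7 --outdir out/` runs everything from the
shell and writes TSV/JSON artifacts plus a text report.

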