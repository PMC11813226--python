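# Methods

This note documents the models, the defaults and why they were chosen,
what the synthetic generator does and does not emulate, and the numerical
decisions that were genuinely open.

## Study design assumed throughout

Four groups — control, challenge (sucrose), challenge + treatment dose 1,
challenge + treatment dose 2 — with the same animals profiled in up to
four tissues (liver, visceral white adipose, skeletal muscle, brain by
default). Animal ids are the cross-tissue join key: every cross-tissue
statistic (shared-DEG concordance, inter-tissue eigengene correlation)
aligns samples by animal, never by column position. Three pairwise
contrasts are analysed per tissue: sucrose vs control, dose 1 vs sucrose,
dose 2 vs sucrose.

## Synthetic data generator

The generator (`crossnet.simulate`) emulates the count-level statistical
structure the downstream stages assume:

- **Noise model.** Per-gene baseline means are log-normal
  (`mean_log = log 150`, `mean_sd = 1`, spanning roughly 5–5000 normalized
  counts); counts are negative-binomial via a gamma–Poisson mixture with
  the mean-dependent dispersion trend `phi(mu) = a0/mu + a1`
  (`a0 = 3`, `a1 = 0.05`, i.e. ~22% CV for well-expressed genes — typical
  bulk RNA-seq values); library sizes are log-normal (`sd = 0.15`) and act
  multiplicatively before sampling.
- **Planted differential expression.** A fraction `frac_sucrose_deg`
  (default 0.15, matching the ~14% DEG rate of a strongly responding
  tissue) of genes receives a signed log2 fold change (`|lfc| ~
  N(1.5, 0.4)`, 60% induced) in the sucrose group. A fraction
  `reversal_frac_d1` (default 0.6) / `reversal_frac_d2` (default 0.3) of
  DEGs is *reversed*: the treated group's mean returns fully to the
  control baseline; non-reversed DEGs retain the sucrose effect in the
  treated groups. Full return-to-control is the planted model; partial
  reversal would be a config extension and is off by default.
- **Shared effects across tissues.** A fraction `frac_deg_shared`
  (default 0.3) of DEGs is planted under the same gene ids in every
  tissue with per-tissue log2FCs correlated at `shared_lfc_corr`
  (default 0.8). This gives the cross-tissue concordance statistic a
  planted truth to recover.
- **Modules and coupling.** Disjoint gene blocks (default 3 per tissue,
  30–60 genes) are driven by per-sample latent factors; gene means are
  multiplied by `exp(amplitude * loading * factor)` (`amplitude = 0.5`,
  `loading = 0.9`). Selected module pairs in different tissues share a
  per-animal factor mixed to a target correlation (`cross_module_corr`,
  default 0.7), so their eigengenes correlate across tissues at
  approximately that value. Module 0's genes are preferentially planted
  as induced-and-reversed DEGs (fraction `module0_deg_frac = 0.8`) so
  that one module per tissue carries the induced-then-suppressed
  enrichment pattern.
- **Not emulated:** read-level structure (FASTQ/alignment), isoform
  usage, batch effects, gene-length bias beyond TPM computation,
  sample dropout, and correlated dispersion outliers. Passing recovery
  tests therefore demonstrates correctness of the statistics under the
  assumed NB + latent-factor world, not robustness to artefacts real
  data may carry.

The default scale is 2000 genes per tissue — a desk-scale stand-in for
the ~19,780 protein-coding genes of a full rat annotation — and 10
animals per group. Fixing `seed` fixes every output bit.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference
over genes positive in all samples (with an explicit 0.5-pseudo-count
fallback when no such gene exists). Dispersion is per-gene method of
moments on normalized counts, pooled within the two contrast groups with
unbiased group variances and floored at 1e-8; there is no trend fitting
or shrinkage. log2FC uses a 0.5 pseudo-offset on zero group means so
estimates stay bounded without shrinkage machinery.

The Wald statistic divides the natural-log mean ratio by the delta-method
SE. Its p-value uses a **t reference with n1+n2−2 degrees of freedom**
rather than a normal: the SE is a plug-in estimate whose sampling noise
makes the statistic t-like at small n, and simulation at 2000 null genes
with 10 vs 10 samples shows the normal reference rejects ~6.7% at the 5%
level while the t reference is calibrated (~5.1%, inside the binomial
99% CI across seeds). BH adjustment is the package's own step-up
implementation, checked against statsmodels.

These simplifications mean DEG counts on real data will differ from
tool-exact DESeq2 runs; none of the validated properties depend on that
parity. The VST stand-in is `log2(count/size_factor + 1)`.

## Reversal and concordance

Percentages are always `100 * overlap / |challenge set|`, rendered at one
decimal by default with an integer mode for report parity with mixed
rounding styles; an empty challenge set yields "not applicable" (`None`),
never 0. The hypergeometric population `N` defaults to the number of
genes tested in the tissue's contrasts; a caller can widen it to a full
annotation universe (`--background`). Which draw-size convention a
published hypergeometric p used is generally not recoverable, so p-values
are compared only qualitatively; the counts and percentages are exact
arithmetic. Concordance excludes genes with a zero log2FC in either
tissue from the sign-agreement percentage and reports Spearman rho as
not-applicable below 3 shared genes.

## Co-expression networks and modules

Correlation is Spearman over all samples of a tissue pooled across
groups (perturbation-responsive modules are the point of the module–DEG
enrichment step, so group structure is deliberately left in), with
p-values from the t approximation and BH across all tested pairs.
Retained edges are positive correlations at FDR < 0.05, cut to the top
decile by rho. The decile is taken **of all tested pairs** by default:
in gene-rich data the FDR filter is then the binding constraint, while
taking the decile of the FDR-significant candidates themselves (available
as `top_frac_basis="candidates"`) concentrates edges on hub genes,
leaves a large share of module genes isolated and demonstrably shatters
planted modules below the size cutoff. The basis in force is logged per
run. Ties in rho break by canonical gene-pair order so runs are
reproducible.

Leiden modularity partitions run on the rho-weighted retained graph with
an exposed, logged seed; communities under 30 genes go to `unassigned`;
module ids are assigned by descending size (M0 largest). The eigengene is
the first right-singular vector of the gene-standardized module
submatrix, unit norm, oriented to correlate positively with the mean
standardized module expression — an arbitrary but fixed convention that
makes cross-run and cross-tissue comparisons stable. Inter-tissue module
correlation uses Spearman on eigengenes aligned by animal id, BH across
all pairs tested.

## Gene-set enrichment

One-sided hypergeometric over-representation through the same kernel as
the reversal statistics; sets are intersected with the universe before
testing and the universe defaults to the genes tested in the relevant
tissue (standard over-representation practice). Depletion testing and
rank-based methods are out of scope.

## Metabolic reaction activity

Models are small BiGG-style JSON (metabolites, reactions with
stoichiometry, bounds, optional GPR string, subsystem). GPR semantics:
AND → min (limiting subunit), OR → sum (isozymes add capacity); genes
missing from the expression table evaluate to 0 with a warning.

Scoring per reaction r and sample: LP-1 maximizes `v_r` under `S v = 0`
and bounds; reactions with `v_max ≤ 1e-9` are blocked and excluded. LP-2
splits every flux into nonnegative forward/backward parts and minimizes
`Σ pen_i (v_i⁺ + v_i⁻)` subject to steady state, bounds, and
`v_r ≥ w · v_max` with `w = 0.95`; the score is `−log(penalty + ε)`,
`ε = 1e-10`. Penalties are `1/(1 + expr)` for gene-associated reactions
and 0 for unassociated ones — they contribute no expression evidence —
with a mean-penalty alternative exposed as config. Both LPs use HiGHS;
the implementation is cross-checked in the tests against an independent
absolute-value epigraph formulation to 1e-6, and scaling all bounds by c
shifts scores by exactly −log c (at ε = 0). One score per reaction; no
meta-reaction clustering. Ortholog mapping between species is reduced to
an explicit user-supplied gene-id mapping.

Differential activity: two-sided Wilcoxon rank-sum per reaction — exact
when the smaller group has ≤ 10 samples *and* there are no ties (exact
enumeration is invalid under ties), otherwise the normal approximation
with tie and continuity corrections — BH across reactions, Cohen's d with
pooled unbiased SD, and significant-reaction counts per subsystem and
d-sign. Activity reversal is the fraction of challenge-significant
reactions also treatment-significant with the opposite d sign.

## Pipeline

Stages write plain-text artifacts (TSV/JSON) into the run directory and
are skipped when their outputs exist and nothing upstream ran; deleting
an intermediate recomputes it and everything downstream. The report
records config hash, seed and package version, and every reported number
is read back from a stage artifact. The pipeline's metabolic stage runs
the bundled toy model with a deterministic model-gene → data-gene mapping
that favours planted reversed DEGs, so treatment effects visibly
propagate into reaction scores; with user data a mapping table is
supplied instead.

## Problem sizes used in validation

Null calibration uses 2000 genes at 10 vs 10 samples; module recovery
uses 3 × 50 genes at loading 0.9 with 40 samples over 20 seeds; coupling
recovery uses 2 tissues × 400 genes with one planted 0.7 coupling over
40 animals; reversal recovery uses 2000 genes with strong planted
effects (|lfc| ~ N(2, 0.3), baseline mean 300) so detection power does
not attenuate the recovered fraction; the LP oracle is the 3-reaction
linear pathway whose optimal penalty (0.95 at w = 0.95, expression 9) is
hand-solvable. These sizes are the package's validation conditions and
are reused by `scripts/acceptance.py`.

## Known limitations

- The DE stand-in is not DESeq2; counts of borderline DEGs will differ.
- The sign-agreement and reversal estimates are attenuated by detection
  power; recovery is tested under strong planted effects.
- Eigengene orientation is convention-bound; only correlations and their
  signs relative to the same convention are meaningful.
- The scoring LPs are dense and desk-scale; genome-scale models (10k+
  reactions) are out of scope.
- The generator's independence assumptions (genes conditionally
  independent given latent factors) understate real co-expression
  background; FDR behaviour on real data will be less clean.
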