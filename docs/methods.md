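# Methods

## The model

diffstab infers differential mRNA stability from standard RNA-seq by
exploiting the split between intronic and exonic reads. Intronic reads come
from unspliced pre-mRNA and track transcription; exonic reads come mostly
from spliced mature mRNA, whose steady-state level reflects both
transcription and degradation. For one gene across samples, with **p** the
pre-mRNA abundance vector, **m** the mature abundance, **γ** the stability
(inverse degradation rate) and φ a processing-capacity constant, the model
assumes a power law

    log m = b · log p + log φ + log γ,        0 ≤ b ≤ 1,

where the exponent *b* captures coupling between transcription and
processing: *b* = 1 means no coupling; *b* < 1 means the processing rate
saturates as transcription rises. Stability is modelled log-linearly in
sample covariates, log γ = Xβ + α₀, so β is the differential log stability
per covariate unit. Observed counts are negative binomial around means

    λ_int = p · l · s_int,      λ_exo = m · l′ · s_exo,

with gene-length factors l, l′ and per-pseudo-library size factors s. Taking
logs stacks each gene's 2n observations (intronic block first) into one GLM
with log link; the covariate structure is carried entirely by the *expanded
design matrix*, and β appears only on the exonic block, so it measures
exonic excess beyond what b-scaled intronic signal predicts.

Two variants are provided:

* **full** — one latent log-abundance per sample (design
  `[[I_n, 0, 0], [b·I_n, 1, X]]`, first column replaced by an all-ones
  intercept, an equivalent reparameterization). p = n + 1 + k coefficients.
* **simplified** — pre-mRNA abundance regressed on the same covariates,
  log p = Xω + ρ (design `[[1, X, 0, 0], [1, b·X, 1, X]]`,
  p = 2k + 2). Preferred for large cohorts, where the full model's latent
  count grows with n, and generally whenever covariates explain most
  pre-mRNA variance.

## Fitting pipeline

1. **Filtering.** Genes need ≥ 10 total intronic and ≥ 10 total exonic reads
   (defaults; an NB fit on an all-zero row is undefined), and a user-supplied
   exclusion list (e.g. cell-cycle genes, which violate the steady-state
   assumption) is honoured.
2. **Size factors.** Median-of-ratios over the stacked gene × 2n matrix,
   treating each (sample, feature-type) pair as a pseudo-library, then
   renormalized to geometric mean 1 within the intronic and exonic blocks so
   the global intron/exon scale lands in the gene-level intercepts.
3. **Coupling exponent.** *b* is profiled on [0, 1] by bounded scalar search
   maximizing the total NB log-likelihood under a constant-stability design
   (no β columns), with per-gene dispersions re-profiled at each candidate
   *b* on a coarse grid (a `fast_bias` option freezes them at b = 1). The
   **condition-level (simplified) profile is the default in both modes**:
   the per-sample-latent profile estimates n incidental parameters per gene
   and is visibly attenuated toward small b at small n (an incidental-
   parameters effect), while the condition-level profile is near-unbiased in
   simulation. The per-sample profile remains available
   (`bias_mode="full"`).
4. **Dispersion.** Per-gene profile maximum likelihood over α ∈ [1e-8, 10]
   (coarse geometric grid + batched golden-section refinement), then
   rescaled by N/(N−p). The rescaling is the ddof analogue for a
   variance-type parameter: the raw profile MLE is biased low by roughly
   (N−p)/N because the fitted means absorb p degrees of freedom, which
   otherwise makes downstream Wald inference anticonservative. No cross-gene
   shrinkage or trend fitting is applied, so single-gene dispersions remain
   noisy at small n — the price of keeping genes independent.
5. **Per-gene GLM.** Batched Fisher-scoring IRLS across genes (shared
   design, per-gene α), log size factors as offsets, per-gene step halving
   on likelihood decrease, convergence at relative log-likelihood change
   < 1e-8 (max 100 iterations). Standard errors come from the inverse
   observed Fisher information.
6. **Inference.** Wald z-tests per stability coefficient (two-sided,
   standard normal), Benjamini–Hochberg correction across genes within each
   coefficient, and a −1/0/+1 status call (destabilized / unchanged /
   stabilized) at the chosen FDR. Coefficients are reported as log2
   fold-changes (natural-log estimates divided by ln 2). Confidence
   intervals (`conf_int`) use the Student-t quantile at the residual degrees
   of freedom 2n − p rather than the normal quantile, because the Wald
   variance is evaluated at an estimated dispersion; the two references
   coincide as n grows.

## Companion models

* **Decay time-courses** (`DecayTimecourseModel`): for transcription-chase
  data (BrU/4sU labelling followed over time), mature counts are fitted with
  design `[1, cell, time, cell:time]`. Log-abundance is linear in time under
  exponential decay, so `cell:time` is the differential decay rate per hour
  (natural log); size-factor normalization absorbs the *median* gene's
  decay, so rates are measured relative to the gene average — the usual
  convention for such designs.
* **Purity deconvolution**: `build_deconvolution_covariates` constructs
  `[stage, impurity, stage:impurity]` with impurity = 1 − purity. The stage
  coefficient is then the stage effect at zero impurity, attributable to
  malignant cells rather than to cell-composition drift. Stage is expected
  dichotomized (low = 0, high = 1).
* **Regulon enrichment** (`RegulonEnrichmentModel`): for each RNA-binding
  protein or miRNA family, a binomial GLM models the share of a gene's 3′-UTR
  binding sites belonging to the focal factor (successes = focal sites,
  failures = all other factors' sites) as a function of the gene's stability
  status treated as a numeric −1/0/+1 trend. Using total sites as the
  denominator controls for covariates that inflate binding generally (UTR
  length above all). miRNA sites are exact 8-nt target-sense seed matches in
  single-exon, isoform-shared 3′ UTRs, counted only if they fit entirely
  within 2000 nt of the stop codon; overlapping matches count separately.
  Activity scores flip the coefficient sign for destabilizing factors so
  positive activity always reads "regulator more active".

## Synthetic data

The generators draw data from exactly the generative chain above:
per gene, baseline log p ~ N(4, 1.5²) (natural logs), covariate effects
ω ~ N(0, 0.5²), stability effects β ~ N(0, beta_sd²) with beta_sd = 0.5 by
default, log φ ~ N(0, 0.5²), length factors LogNormal(0, 0.5), NB dispersion
0.1, size factors uniform on (0.5, 2) per pseudo-library, and b = 1 unless
stated. These values were fixed once to produce realistic count ranges
(median intronic depth in the tens, upper range in the thousands) and are
not revisited per experiment. Two deliberate simplifications: log p contains
no per-sample variation beyond the covariates (matching the simplified
model's assumption), and no alternative splicing, 3′-UTR switching or
cell-mixture convolution is simulated. Passing tests therefore demonstrate
correct inference under the model's own assumptions — not robustness to the
full messiness of tissue RNA-seq.

The transcription-only generator multiplies p by a fold change in one
condition while holding γ fixed: at b = 1 the expected exon/intron ratio is
unchanged, so a correct stability model must report no signal. The
time-course generator decays labelled RNA exponentially from a random
time-zero level; the regulon generator draws site totals Poisson(20)+1 and
focal successes binomially with log-odds linear in status.

## Validation suite and problem sizes

The acceptance script and test suite validate, at sizes chosen to finish in
minutes on one CPU: exact equality of all design matrices with loop-based
block constructions; per-gene likelihood optimality against 200×200
brute-force coefficient grids; recovery of b ∈ {0.3, 0.5, 0.7, 1.0} within
±0.05 (500 genes, 6+6 samples); β recovery and t-interval coverage (2000
genes); null calibration over 20 seeds; invisibility of a 4-fold
transcription-only shift; full-vs-simplified agreement (1000 genes, 4+4);
2 h-vs-4 h time-course recovery within 3 SE (25 focal genes among 475 null
genes — a 5% differential minority, consistent with median normalization's
assumption that most genes are unchanged); regulon CI coverage over 100
replicates plus a 150-factor null; and byte-level determinism.

## Known limitations

* **Full-mode small-sample inference.** With n+1 incidental latent
  abundances per gene, residual degrees of freedom are n − k − 1; per-gene
  Wald inference in full mode is anticonservative at small n even after the
  dispersion df-correction. Use the simplified mode when calibrated per-gene
  error rates matter at small n; the full mode's point estimates remain
  excellent (they correlate > 0.99 with simplified-mode estimates in
  simulation).
* **Estimation noise floor.** With NB dispersion α, a log fold-change
  estimated from n_c samples per condition has variance at least
  2α·(2/n_c) regardless of depth; expectations for recovery correlations
  must respect this floor.
* **Steady-state assumption.** Stability is inferred from level ratios, so
  genes far from steady state (cell cycle, acute induction) should be
  excluded by the caller.
* **No dispersion shrinkage.** Genes are fitted independently by design;
  with very few samples, borrowing strength across genes (as
  empirical-Bayes engines do) would give tighter dispersions at the cost of
  cross-gene coupling.
* **b is global.** The coupling exponent is estimated once per dataset, not
  per gene; gene-specific processing saturation is absorbed into residual
  dispersion.
* **Exponent profiling assumes mostly-constant stability.** The
  constant-stability profile absorbs unmodelled differential-stability
  variance more cheaply at larger b (shifting a gene's abundance effect by
  δ costs δ² on the intronic block but recovers (bδ)² of exonic misfit), so
  b̂ inflates toward 1 when stability effects are widespread and strong. In
  simulation the profile peaks exactly at the true b when stability is
  constant, at ~0.8 for true b = 0.7 with β ~ N(0, 0.25²), and at 1.0 with
  β ~ N(0, 0.5²). When a large differential-stability signal is expected,
  estimate b on a reference subset of genes or supply a known b via
  ``fit(b=...)``.
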