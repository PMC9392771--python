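# diffstab

Differential mRNA stability from exonic and intronic RNA-seq read counts.

## The problem

Steady-state RNA-seq confounds transcription with degradation: a transcript
can be abundant because it is made fast or because it decays slowly. Reads
falling in purely intronic regions, however, come from unspliced pre-mRNA
and track transcription alone, while reads in constitutive exons track the
mature transcript, shaped by both processes. The ratio of the two carries
the degradation signal. diffstab turns this observation into a statistical
model for *differential* stability — which transcripts are stabilized or
destabilized between conditions (tumour vs normal, knockout vs parental,
high vs low stage), with honest uncertainty — for bulk cohorts of any size.

## The model

For a gene across *n* samples, with pre-mRNA abundance **p**, mature
abundance **m**, stability **γ** and processing capacity φ:

    log m = b · log p + log φ + log γ            (power-law coupling, 0 ≤ b ≤ 1)
    log γ = X β + α₀                             (stability log-linear in covariates)

Observed intronic and exonic counts are negative binomial with means
`p·l·s_int` and `m·l′·s_exo` (gene-length factors *l*, *l′*; per-library
size factors *s*). Stacking each gene's intronic and exonic observations
into one 2n-row GLM with log link, all latent structure moves into an
expanded design matrix; the stability coefficients **β** load only on the
exonic rows, so they measure exonic excess beyond what *b*-scaled intronic
signal predicts. The exponent *b* is estimated once per dataset by profile
likelihood under a constant-stability design. A full variant (one latent
abundance per sample) and a simplified variant (abundance regressed on the
covariates; recommended for large cohorts) are provided, along with a decay
time-course model, a tumour-purity deconvolution design, and regulon
enrichment for RNA-binding proteins and miRNA seed families.

## Worked example

```python
import numpy as np
import diffstab as ds

# simulate 6 tumour vs 6 normal samples with known stability effects
X = ds.CovariateMatrix(np.repeat([0.0, 1.0], 6)[:, None], ["condition"])
data, truth = ds.simulate_stability_dataset(
    1000, X, beta_sd=0.5, dispersion=0.1, seed=1)

model = ds.DifferentialStabilityModel(data, X, mode="simplified")
results = model.fit(fdr=0.05)
print(results.summary())
```

This prints:

```
Differential mRNA stability model
================================================
mode:                 simplified
genes:                1000
samples:              12
coupling exponent b:  0.9996
converged gene fits:  999/1000
FDR threshold:        0.05
  condition: 91 stabilized, 100 destabilized (q <= 0.05)
```

The profiled coupling exponent (0.9996) recovers the generator's default
b = 1 (no transcription–processing coupling); 191 of 1000 genes are called
differentially stable at FDR 0.05, and the per-gene table
(`results.table`) carries log2 fold-changes of stability, standard errors,
Wald statistics, p/q-values and −1/0/+1 status calls. Checking against the
simulated truth:

```python
est = results.log2fc("condition") * np.log(2)     # back to natural log
ci = results.conf_int("condition") * np.log(2)
print(round(np.corrcoef(est, truth.beta[:, 0])[0, 1], 3))   # 0.436
covered = (truth.beta[:, 0] >= ci[:, 0]) & (truth.beta[:, 0] <= ci[:, 1])
print(round(covered.mean(), 3))                             # 0.94
```

The correlation with truth (0.436) reflects the deliberately hard setting —
twelve samples at dispersion 0.1 puts a hard floor on per-gene precision —
while the 95% intervals cover the truth for 94% of genes: the estimator
knows its own uncertainty.

The same pipeline runs from the shell on TSV count tables:

```bash
diffstab simulate --preset effect --seed 1 --n-genes 1000 --out demo/
diffstab run --exonic demo/exonic.tsv --intronic demo/intronic.tsv \
    --samples demo/samples.tsv --design condition --mode simplified \
    --out demo/results.tsv
diffstab regulon --results demo/results.tsv --utrs utrs.fa \
    --factors factors.tsv --out demo/enrichment.tsv
```

Each run writes a JSON manifest (estimated b, gene counts before/after
filtering, configuration) next to the results. File formats are documented
in `FORMATS.md`.

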