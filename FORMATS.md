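# File formats

All tables are UTF-8, tab-separated, with a header row. Floats are written
at six significant digits.

## Count matrices (`--exonic`, `--intronic`)

First column `gene_id`, remaining columns one per sample (header = sample
ID). Entries are non-negative integers. The two tables are intersected on
genes and samples; ordering follows the exonic file.

## Sample table (`--samples`)

Column `sample_id` plus covariate columns. Covariates must be numeric;
binary factors 0/1-coded (condition: 0 reference / 1 alternative; sex 0/1;
stage dichotomized low = 0 / high = 1), purity in [0, 1], time in hours.

## Stability results (`diffstab run --out`)

Columns, in order:

| column             | meaning                                             |
|--------------------|-----------------------------------------------------|
| `gene_id`          | gene identifier                                     |
| `coefficient`      | design variable the row refers to                   |
| `log2FC_stability` | differential stability, log2 per covariate unit     |
| `SE`               | standard error of `log2FC_stability`                |
| `stat`             | Wald z statistic                                    |
| `pvalue`           | two-sided normal p-value                            |
| `qvalue`           | Benjamini–Hochberg adjusted p (per coefficient)     |
| `status`           | −1 destabilized / 0 unchanged / +1 stabilized (FDR) |
| `dispersion`       | per-gene NB dispersion α                            |
| `converged`        | whether the per-gene fit converged                  |

A JSON manifest `<out>.manifest.json` records the estimated coupling
exponent `b_hat`, mode, design, filters, gene counts before/after
filtering, and package version.

## UTR sequences (`--utrs`)

FASTA; record ID = gene ID; sequence is the 3′ UTR, 5′→3′, starting at the
first base after the stop codon (DNA or RNA alphabet; U is normalized to T).

## Factor table (`--factors`)

Columns `factor_id`, then `site_sequence` (8-nt target-sense site, one row
per site variant) and/or `direction` (`stabilizer` / `destabilizer`).
Precomputed per-gene site counts can be supplied instead via `--sites`
(first column `gene_id`, one column per factor).

## Enrichment results (`diffstab regulon --out`)

Columns `factor_id`, `coefficient` (log-odds of the focal factor's site
share per status unit), `SE`, `pvalue`, `qvalue`, `direction`, `activity`
(sign-corrected coefficient; positive = regulator more active).

## Simulation output (`diffstab simulate --out DIR`)

The same dialects as above (`exonic.tsv`, `intronic.tsv`, `samples.tsv`)
plus `truth.tsv` with the generating parameters (true β, dispersion) and a
`manifest.json` with preset and seed.
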