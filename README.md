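# scrhythm

Diurnal rhythmicity inference for single-cell transcriptomic time courses.

The package implements an end-to-end, fully synthetic-testable pipeline for
detecting around-the-clock gene expression changes in a design of four
Zeitgeber timepoints (ZT0/6/12/18) with three biological replicates each and
several immune cell types of unequal abundance:

- **`scrhythm.simulate`** — deterministic generators for sparse single-cell
  count matrices (negative-binomial counts, log2-scale cosine rhythms,
  expression-linked logistic dropout, per-cell size factors, an antiphase
  clock-gene panel), cosine binding time series, and promoter sequences with
  planted motifs. Ground truth is returned for recovery scoring.
- **`scrhythm.pseudobulk`** — per-replicate aggregation, median-of-ratios
  size factors, a two-group negative-binomial Wald test (method-of-moments
  dispersions shrunk 50/50 toward an `a0 + a1/mean` trend), DEG counting per
  cell type with the ≥250-cells inclusion rule, a minimum-detectable-log2FC
  power bound, and log2FC→percent conversion.
- **`scrhythm.hurdle`** — cell-level two-part hurdle model (ridge-penalized
  logistic detection + OLS on log2 expression among detected cells) with a
  standardized cellular-detection-rate covariate, per-timepoint one-vs-rest
  shift contrasts (2-df LRT), the peak-and-trough rhythmicity filter
  (≥2 significant timepoints, at least one positive and one negative shift),
  a Wilcoxon rank-sum cross-check, and one-vs-rest marker calling.
- **`scrhythm.ordering`** — k-means temporal ordering of samples from a
  small gene signature, with majority-timepoint cluster labels and a
  concordance score.
- **`scrhythm.cosinor`** — fixed-period cosinor (exact least squares,
  zero-amplitude F test) and free-period fitting (0.01-h RSS grid plus
  golden-section refinement).
- **`scrhythm.motifs`** — E-box (CACGTG, optionally CANNTG) scanning with
  BED6/TSV output; both motif classes are reverse-complement symmetric, so
  forward-strand scanning covers both strands.
- **`scrhythm.io`** — Matrix Market / TSV / FASTA / YAML readers and
  writers, data containers, and threshold configuration.

Default thresholds follow the study design the pipeline emulates: adjusted
p < 0.05 throughout; log2FC cutoffs 0.2 (pseudobulk between timepoints),
0.58 (adult vs aged), 0.15 (cell level, ≈10% change); min.pct 0.05; marker
calling at 25% expression and log2FC 0.405.

## CLI

All subcommands read plain-text inputs and write TSV results:

```sh
scrhythm simulate --config sim.yaml --out data/ --seed 1
scrhythm pseudobulk-de --counts data/ --contrast ZT0:ZT12 --out de.tsv
scrhythm deg-counts --counts data/ --contrast ZT0:ZT12 --out degs.tsv
scrhythm rhythm-call --counts data/ --celltype typeA --out rhythm/
scrhythm temporal-order --counts data/ --genes signature.txt --k 4 --seed 7 --out order.tsv
scrhythm cosinor --series series.tsv --period 24
scrhythm cosinor-free --series series.tsv --lo 20 --hi 28
scrhythm scan-ebox --fasta promoters.fa --noncanonical --out hits.tsv --bed hits.bed
```

`--verbose` (before the subcommand) logs debug detail to stderr.

## Notes and limitations

- The pseudobulk test is a deliberately simplified NB Wald pipeline (no LFC
  shrinkage, no independent filtering); the group means are per-group
  maximum-likelihood fits, which makes the test exactly symmetric under
  swapping contrast groups.
- The power bound uses a log-scale two-sample t approximation with a
  user-supplied variance, solved from the noncentral-t power equation.
- The cell-level shift contrast applies the log2FC threshold to the
  one-vs-rest shift estimate; an alternative reading (two-group ZT-vs-ZT
  fold change) is not implemented.
- Free-period cosinor on six-point series yields point estimates only; the
  profile-RSS curve is returned instead of confidence intervals, which are
  unreliable at that sample size.
- Simulator dropout and dispersion defaults are conventions, not estimates
  from any particular dataset.
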