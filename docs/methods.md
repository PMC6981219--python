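# Methods

## Model and procedure

`consensusde` analyses a gene × sample matrix of raw read counts under a
two-group design (control vs treatment; the first declared condition label
is the reference). The pipeline has four stages:

1. **Normalization.** Eight methods, two families:
   - *Factor methods* return per-sample relative **depth factors** with
     geometric mean 1: TMM (doubly trimmed, variance-weighted mean of
     log-ratios to a reference sample, times the library-size ratio),
     upper-quartile (75th percentile of nonzero counts), median of nonzero
     counts, and PoissonSeq-style iterative depth estimation. Multiplying
     one sample's counts by *c* multiplies its pre-rescaling factor by *c*
     — factors are depth estimates, not edgeR-style composition
     corrections. Effective depth is `factor × geometric-mean library
     size`; its natural log is the offset handed to count models.
   - *Matrix methods* return a transformed expression matrix: TMM-CPM
     (counts per million on TMM effective depths), RPKM (per kilobase of
     collapsed gene model per million reads), full-quantile (rank-wise
     substitution by the mean of sorted columns), and RUV (subtraction of
     k hidden factors estimated by SVD of control-gene residuals on the
     log scale).
2. **Testing.** Five models per normalization: negative-binomial Wald,
   robust negative-binomial likelihood ratio (both share one dispersion
   fit per normalization), voom-style precision-weighted moderated *t*,
   Mann–Whitney, and Welch *t* on log2 values. All tests are two-sided.
   p-values are Benjamini–Hochberg adjusted within each (normalization,
   model) cell.
3. **Aggregation.** Per model, q-values are averaged across
   normalizations (arithmetic mean); a gene is a target of a model when
   its mean q is strictly below the threshold (default 0.25).
4. **Consensus.** A gene is called when it is a target of at least
   `k_required` models (default all five). Direction is the sign of the
   median log2 fold change across all cells; exactly zero is labelled
   "ambiguous".

### How normalizations feed models

Nothing forces a factor-producing normalization and a count model to
compose, so the pairing is made explicit: factor methods enter the count
models (NB Wald/LRT) as natural-log offsets and the rank/t tests as
factor-divided counts; matrix methods enter the rank/t tests directly and
the count models as the matrix **rounded to integers** with zero offsets —
an approximation (the NB variance model no longer strictly holds for
rescaled values) that is recorded per cell in the run summary. voom
receives the rounded matrix with its own column totals as effective depths.
This keeps all 40 cells defined; the caveat travels with the output.

## Dispersion estimation (shared by the two NB models)

NB variance convention: `var = mu + phi mu^2`.

- **Raw per-gene estimate** by within-group moments of depth-adjusted
  counts: `phi_raw = (s2_pooled - mu_hat * mean(1/d)) / mu2_hat`, clipped
  at 0, where `mu2_hat` is the unbiased estimate of `mu^2`
  (`mu_hat^2 - s^2/n` per group, floored at `mu_hat^2/4` — the unfloored
  version explodes when the two terms nearly cancel).
- **Trend** `phi(mu) = a/mu + b` fit by robust least squares (soft-L1
  loss, nonnegativity bounds) over genes with positive raw dispersion;
  fewer than 3 such genes triggers a global-median fallback with a
  warning.
- **Shrinkage**: final dispersion is the geometric mean of raw and trend
  (weight 0.5 each on the log scale), with the raw log corrected for
  Jensen bias by `log(df/2) - digamma(df/2)`. Genes with zero/undefined
  raw dispersion take the trend value.

The two bias corrections matter: with true dispersions the NB Wald test
rejects at 0.052 at nominal 0.05 (n = 6/group, 2000 null genes); with
uncorrected plug-in moments it rejects at ~0.066, and with the corrections
at ~0.057.

## The five models

- **NB Wald**: group means fit by MLE with fixed gene-wise dispersion and
  offsets (a damped fixed-point iteration that reduces to the exact sample
  mean under equal offsets, so the reported log2 fold change is exactly
  the log2 ratio of group means there). Statistic = log-fold-change over
  its SE from observed Fisher information; standard-normal reference. No
  fold-change shrinkage.
- **Robust NB LRT**: full (two means) vs null (one mean) likelihood ratio
  at fixed dispersion, chi-square(1) reference. Observations with
  first-pass Pearson residual above 2.5 are down-weighted by `2.5/|r|` in
  fits and likelihoods, so one gross outlier cannot drive significance.
- **voom moderated t**: `y = log2((count+0.5)/(depth+1) * 1e6)`; lowess
  trend of sqrt residual SD on mean log-count, evaluated at each fitted
  observation, gives inverse-variance precision weights (`trend^-4`);
  weighted group means and residual variances are empirical-Bayes
  moderated (scaled-F prior fitted by digamma/trigamma moment matching)
  and referred to a t distribution with `d0 + d_g` df. Panels under 10
  genes fall back to an unweighted Welch t with a warning.
- **Mann–Whitney**: exact two-sided p by full enumeration when the total
  sample count is ≤ 10 and the gene has no ties, else the normal
  approximation with tie and continuity corrections. The reported fold
  change is display-only.
- **Welch t**: on `log2(x + 0.5)` values, Satterthwaite df. Zero-variance
  degeneracies: equal means → p = 1; unequal means → p = 0, flagged.

Genes with zero counts in every sample are never dropped: they receive
p = q = 1, lfc = 0 and an `all-zero` flag, keeping the gene universe
identical across cells so the consensus is well defined.

## Synthetic data generator

`simulate_dataset` draws
`counts[g, j] ~ NB(mu_g * 2^(x_j * lfc_g) * depth_j * exp(unwanted), phi_g)`
as a gamma–Poisson mixture, with one integer seed threading all
randomness. Defaults (chosen once as realistic bulk-RNA-seq scale):

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 15000 | genome-scale panel |
| `n_per_group` | 6 | replicates per condition |
| `baseline_meanlog/sdlog` | 4.0 / 1.5 | log-normal baseline means (median ≈ 55 counts, heavy right tail) |
| `disp_a`, `disp_b` | 3.0, 0.1 | trend `phi = a/mu + b`: decreasing dispersion, asymptote 0.1 |
| `libsize_sdlog` | 0.3 | ~35% spread in sequencing depth |
| `frac_de` | 0 | planted fraction; DE genes get `±(1.0 ± N(0, 0.25))` log2 FC, clipped at ≥ 0.5 |
| `n_unwanted_factors` | 0 | optional hidden batch factors (`N(0, 0.5)` gene loadings) |

The generator emulates gene-wise NB counts with a mean–dispersion trend,
depth heterogeneity, symmetric planted effects bounded away from zero, and
hidden factors. It does **not** emulate isoform structure, read-level
artifacts (GC/length bias within a sample), count correlation between
genes, or outlier samples; passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
every pathology of real libraries. Gene lengths are simulated
(log-normal, median ≈ 1.5 kb) only so length-dependent methods are
exercised; simulated counts do not actually depend on them.

## Numerical choices

- Pseudo-count 0.5 for every log transform.
- Upper-quartile percentile convention: linear interpolation at index
  `0.75 (n-1)` over nonzero counts.
- TMM: trims keep the central 40% of M and 90% of A by rank; the
  reference sample is the one whose upper quartile of relative abundances
  is closest to the mean upper quartile; weights are inverse delta-method
  variances on the relative-abundance scale (`1/(1/p_j + 1/p_r)`), which
  makes the factors exactly scale-equivariant.
- Full-quantile ties are broken by input order (stable sort), so each
  output column is an exact permutation of the reference vector and the
  transform is exactly idempotent; tie-averaging would violate both.
- PoissonSeq iteration: depth-only expected counts, least-variable half as
  the null set, tolerance 1e-8, max 20 iterations, non-convergence flagged.
- RUV: empirical controls = the half of genes with the largest first-pass
  Welch-t p-values; `k` must satisfy `k < n_samples - 2`. Group-centering
  means only the within-group component of a hidden factor is
  recoverable; its between-group component is confounded with treatment
  and deliberately left alone.
- BH within cell; q-values are exactly the step-up
  `min_{j>=i} p_(j) m / j` capped at 1.
- Strict inequality at the mean-q threshold (0.25 is *not* called).
- Consensus boundary behavior is monotone by construction: raising the
  threshold or lowering `k_required` can only add calls.

## Validation conventions and problem sizes

The test suite checks calibration and recovery at desk scale: 2000-gene
null panels (n = 6/group, 20 replicates) for type-I error, a 5000-gene
panel with 10% planted effects for fold-change and dispersion-trend
recovery, and 15–20 replicate 800-gene grids for consensus error control.
Rejection rates are asserted as replicate means within the single-replicate
99% binomial interval around 0.05. Uniformity of null p-values is checked
by Kolmogorov–Smirnov at the 1% critical value (matching the 99%-interval
convention); for the Mann–Whitney test — whose p-values at n = 6/group are
discrete and conservative, hence never uniform — the check is the
one-sided KS distance against super-uniformity, i.e. validity
(`P(p <= t) <= t`), which is the property FDR control actually needs.

## Known limitations

- Two-group designs only: no covariates, pairing, or multi-factor
  contrasts.
- The Mann–Whitney model has an attainable p-value floor at small n
  (2/924 exact at 6 + 6), so on large gene universes its BH-adjusted
  q-values may never cross the mean-q threshold; as the strictest member
  of the consensus it then dominates the final call count. This is a
  property of rank tests, not a defect, but it makes consensus power at
  n = 6 modest.
- Matrix-normalized values rounded into count models are an approximation
  (flagged per cell); interpret those cells' dispersion estimates with
  care.
- No gene pre-filtering by expression is applied, which inflates the
  tested universe relative to pipelines that filter; all-zero genes are
  retained (with p = 1) by design.
- The moment/trend dispersion estimator targets calibration at realistic
  bulk scales; at very small panels (tens of genes) the trend fit is
  unstable and falls back to a global median.
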