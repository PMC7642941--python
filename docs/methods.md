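# Methods

This note documents the models, numerical choices and limitations of
`pathpartblup`. Notation: `n` individuals, `p` SNPs, dosage matrix `X` with
entries 0/1/2, allele frequency `f_j` per SNP.

## Kinship construction

`compute_kinship` centers each dosage column by `2 f_j` and scales it by
`[2 f_j (1 - f_j)]^(alpha/2)`, then forms `K = Z Z' / p` over the chosen SNP
subset. `alpha = 0` (default) leaves dosages unstandardized, so a SNP's
expected contribution to heritability scales with its heterozygosity;
`alpha = -1` reproduces the standardized-genotype (correlation-style)
kinship. Centering is applied even though the bare cross-product formula
does not show it: the random-effect model requires mean-zero columns for the
intercept to capture the population mean (a `raw_crossproduct` switch
restores the literal formula). Two normalizations are supported: divide-by-p
(default) and rescaling to unit mean diagonal. Divide-by-p makes the
partition identity exact,

```
p K_all = p_m K_m + p_!m K_!m
```

for any disjoint SNP split — the complement kernel is therefore derived from
this identity rather than recomputed, which is both faster and exactly
consistent. Missing dosages are imputed to `2 f_j` (the column mean); the
count is logged.

## REML

The restricted log-likelihood of `V = sum_k sigma2_k K_k + sigma2_e I` with
fixed effects `X beta` profiled out is

```
lR = -1/2 [ (n-r) log 2pi + log|V| + log|X'V^-1X| + y'Py ],
P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.
```

`fit_reml` maximizes it with average-information (AI) updates
`theta <- theta + AI^-1 s`, where `s_k = -1/2 [tr(P K_k) - y'P K_k P y]` and
`AI_jk = 1/2 y'P K_j P K_k P y`, with three safeguards that matter in
practice:

* **Step-halving line search** on the AI direction: far from the optimum the
  AI step can overshoot; the step is halved (up to 12 times) until the
  likelihood increases, else the iteration falls back to the EM update
  `theta_k <- theta_k + theta_k^2 (y'P K_k P y - tr(P K_k))/n`, itself halved
  toward the current point if needed (EM is ascent in exact arithmetic but
  not in floating point near boundaries).
* **Active-set boundary handling**: a component pinned at the variance floor
  whose gradient points further down is removed from the AI system for that
  iteration. Without this, a near-zero component makes every AI step fail
  and the fit crawls on EM for hundreds of iterations.
* **Variance floor** of `1e-8 x var(y)`: variances are clamped, never
  negative, which is how the [0,1] heritability constraint is enforced
  without breaking likelihood monotonicity.

Convergence is `|delta lR| < 1e-6`, confirmed by an EM probe step (an AI step
that merely stalls on a ridge is not mistaken for a stationary point); the
iteration cap is 500 and non-convergence is reported, not raised. Warm
starts (e.g. a GBLUP fit split by SNP fraction) cut typical two-kernel fits
to under ten iterations.

Because the default kinship is not unit-diagonal, variance components are
reported as heritabilities after weighting by each kernel's mean diagonal:
`h2_k = sigma2_k d_k / (sum_j sigma2_j d_j + sigma2_e)`, `d_k = mean diag
K_k`. This equals the plain variance ratio after reparametrizing to
unit-diagonal kernels (the fit itself is invariant to that rescaling). The
proportion of genomic heritability is `h2_m / (h2_m + h2_!m)`; it is
undefined (reported missing) when every genetic variance sits at the floor.

## Prediction

Held-out genomic estimated breeding values are the conditional means

```
g_test = sum_k sigma2_k K_k[test,train] V_train^-1 (y_train - X_train beta),
```

the genetic value only — no fixed-effect contribution. Cross-kinships are
the full-sample matrices sliced by fold (allele frequencies are not
recomputed per training fold; a strict train-only variant is a one-line
change in `compute_kinship` usage but was not made the default, matching how
kinship-based cross-validation is usually run). This formula is verified in
the tests against an independent Henderson mixed-model-equations solve.

## Cross-validation and metrics

10-fold, one-fold holdout, repeated 5 times (50 CVs); the identical fold plan
serves both model classes, so per-CV predictive abilities are paired.
Variance components are refit within every training fold. Metrics per CV:
predictive ability `r(GEBV, BLUE)`; reliability `r^2 / h2` with `h2` from the
full-data fit of the same model class (one reliability scale per
trait-model); bias slope from regressing BLUE on GEBV (1 = unbiased); and an
aggregate RMSE, the square root of the mean per-CV mean squared difference.
Folds whose GEBVs are numerically constant (all variances at the floor;
standard deviation below `1e-6 x sd(BLUE)`) yield missing `r`/slope and are
excluded with a logged count — correlations against floor-level numerical
noise would be meaningless.

Model comparison is a one-sided test of mean(`r_Multi - r_GBLUP`) > 0. The
default is the one-sample t-test on the paired differences; an unpaired
Welch variant is available. ("Paired" and "Welch-unequal-variances" are
mutually exclusive; pairing matches the shared-fold design, so it is the
default.) A degenerate all-equal difference vector returns p = 1 (or 0 for a
constant positive difference).

## Phenotype preparation

Raw replicated measurements pass through, in order: (1) outlier removal by
studentized deleted residuals under the mixed model `value = accession
(fixed) + replicate (random) + error`, (2) Box-Cox transformation, (3) GLS
BLUE estimation. The deletion residuals use the exact GLS leave-one-out
identity `t_i = (Py)_i / sqrt(P_ii)` with variance components held at the
full-data REML fit — identical to re-estimating the fixed effects without
each observation and predicting it from its conditional distribution (the
tests verify this against an explicit loop, and against OLS studentization
in the no-replicate-variance limit). The cutoff is the two-sided t critical
value at family-wise 0.05 with Bonferroni correction over the trait's
observations; the statistic's literature leaves the cutoff open, and this is
the standard conservative choice, configurable via `outlier_alpha`. One pass
is taken (no iterative re-detection). Box-Cox lambda maximizes the profile
log-likelihood over the grid [-2, 2] in steps of 0.01, with log at 0;
non-positive values are shifted up with a warning. Ratio traits (relative to
the grand total and to biochemical-family totals) are derived from BLUEs of
absolute traits on the measurement scale; deriving them before vs after BLUE
estimation is not dictated by the data model, and the BLUE-first order keeps
one mixed-model fit per absolute trait.

## Empirical null and decision rule

For a pathway with `p_m` SNPs, a null draw samples non-pathway genes
uniformly without replacement, accumulating each gene's SNPs (same 2.5 kb
buffer rule, deduplicated) until the count reaches `p_m` — the first
overshoot is accepted, so group sizes exceed the target by at most one
gene's SNPs. Genes with zero mapped SNPs are ineligible; SNP-level overlap
with the pathway is allowed (exclusion is by gene). Each group is refit as
the MultiBLUP kernel (complement from the partition identity, warm-started
from the GBLUP fit), recording the proportion of genomic heritability and
the LR. Two one-sided p-values are computed per statistic: the ecdf add-one
estimator `(1 + #{null >= obs}) / (1 + N)` and a one-sample t-test of the
null draws against the observed value. Both are stored; the pipeline default
consumes the t-form, switchable to ecdf. The two differ sharply in meaning:
the ecdf p is calibrated (uniform under the null, as the tests verify at
N = 100 groups), while the t-form tests the *null mean* and is therefore
strongly anti-conservative as N grows — it is kept as the configured default
for fidelity to the described analysis, and every calibration claim in this
package is stated for the ecdf form.

Per trait, each of the three criteria p-values (proportion, LR, predictive
ability) is BH-adjusted across the trait's pathways; a pair is flagged when
all three adjusted p-values are <= 0.10, with an extra annotation tier for
pairs whose predictive-ability gain exceeds 0.05. The reported `delta_slope`
follows the `|slope - 1|` difference convention; raw slopes are stored
alongside. No correction is applied across traits.

## Synthetic data

The generator emulates the study design the pipeline expects, not a
population-genetic model. Genes of 2 kb are tiled along chromosomes with
2.5 kb gaps (typical spacing in a compact plant genome); SNP positions are
uniform along chromosomes; dosages are independent Binomial(2, f) draws with
`f ~ U(maf_range)`, default (0.05, 0.5). Per-SNP effects are Gaussian with
equal variance within the pathway and background groups, acting on centered
unstandardized dosages (consistent with `alpha = 0`). Each genetic component
is rescaled so its realized sample variance equals its target share of a
unit total phenotypic variance — the targets are exact in-sample, which
keeps recovery tests sharp at moderate n. Replicates add a shared Gaussian
replicate effect (`replicate_var`, default 0.1) and i.i.d. residuals.
Defaults (300 individuals, 4000 SNPs, 400 genes, 20 pathways of 10 genes,
pathway share 0.24 of a 0.6 total h2, 3 replicates) describe a desk-scale
panel with realistic structure.

What the generator does *not* model: linkage disequilibrium (an optional
copy-with-mutation block mode exists purely to exercise the kinship-overlap
collinearity diagnostic), population structure, allele-frequency spectra
beyond uniform, multi-trait genetic correlations. Consequently, passing
tests demonstrate the machinery is correct and calibrated under independent
markers; they do not certify behavior under strong LD, where random gene
groups cannot match a pathway's local correlation structure and the null is
known to be only approximate.

## Problem sizes and determinism

The test-suite studies run at n = 60–300 with 1.5k–4k SNPs, 100 null groups
and 10–50 CVs per model; the acceptance script uses the same scales. These
sizes make every study a few minutes on one CPU while keeping the
statistical checks sharp (e.g. the 0.01-resolution grid oracle, or 200
trait-pathway pairs for the Kolmogorov–Smirnov uniformity check). At n = 300
the sampling noise of a single REML heritability estimate is substantial
(SE ~ 0.3 for a genome-wide kernel with ~4000 effective markers), which is
why recovery checks average over 20 traits and summarize the heritability
partition by the proportion of the *mean* estimates — the per-trait ratio is
unstable whenever the background variance lands near its boundary. Every
random draw flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations reproduce byte-identical
artifacts (the pipeline manifest records SHA-256 checksums and skips
up-to-date stages).

## Known limitations

* The empirical null refits only the kernel split, not allele-frequency or
  LD matching of the random groups.
* Externally studentized (per-deletion variance re-estimated) outlier
  residuals would be more robust to masking than the fixed-variance deletion
  residuals used here; with the 100-SD-scale contaminations the pipeline is
  designed to catch, the difference is immaterial.
* The engine accepts any number of kernels, but the pipeline exercises one
  or two; no Bayesian alternatives; no SNP-effect back-solving.
* PCA covariates are computed once on all individuals and reused across CV
  folds (fold-wise recomputation is available via
  `PipelineConfig`), trading a small leakage for fidelity to the single-PCA
  design.
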