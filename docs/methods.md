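# Methods

This note documents the models implemented in `cms-shift`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices that matter for reproducing results.

## Synthetic data model

`syndata` generates every input the pipeline consumes under a single
integer seed; each generator derives its own stream by a fixed offset so
stages can be rerun independently.

**Reference cohort.** Counts are Gamma–Poisson (negative binomial,
Var = m + αm²) rather than Poisson: over-dispersion is the realistic
regime for the variance-shrinkage stage to be meaningful. Each gene has a
baseline log2 abundance ~ N(5, 1.5²); CMS4-labeled samples move a planted
set of genes by ±`de_log2fc_magnitude` (half up, half down); library sizes
are uniform over `library_size_range`. Defaults mirror the kind of cohort
the signature derivation targets: 200 samples on two platforms, ~60/40
split of CMS2/CMS4-labeled samples, 100 planted genes at |log2FC| = 2.
Platform 2 carries a gene-wise additive offset on the log2 mean
(sd `batch_shift_sd` = 0.5) and a multiplicative inflation of the
dispersion (log-sd `batch_scale_sd` = 0.2) — the location/scale form the
adjustment stage assumes. CMS labels are shuffled across platforms so
batch and biology are not confounded.

**Cell-line profiles.** Cell lines start from the epithelial baseline with
a stable N(0, 0.3²) per-gene identity offset (so within-cell-line
centering has structure to remove); treated arms move the planted genes by
`shift_fraction` × the true log2FC. The default layout is the 12-profile
study design (2 lines × 3 treatments × 2 replicates). The replicate noise
model is the same negative binomial as the cohort; nothing is claimed
about the noise of any real replicate series. What the generator does
*not* emulate: gene–gene co-expression beyond what the subtype axis,
treatment axis and cell-line identity induce, gene-length effects,
isoform structure, or count zero-inflation. Passing tests therefore show
the pipeline recovers planted structure under its own assumptions, not
that real data satisfy those assumptions.

**Assay tables.** Dilution assays draw responses ~
Binomial(n_wells, 1 − (1−f)^dose) — the exact Bernoulli-per-cell single-hit
form, not the Poisson approximation, matching the fitter. Meta-analysis
studies have log-effects y_i ~ N(μ, τ² + v_i) with v_i uniform on
`v_range`; a chosen fraction is emitted without CI but with the two-sided
Wald p, exercising the missing-CI reconstruction. Survival times are
exponential with a group-2 hazard multiplier and independent exponential
censoring.

## Preprocessing

RPM/log2 uses a +1 pseudocount inside the log (zero counts map to 0; the
transform is invariant to scaling a column's counts). The batch model is
the parametric empirical-Bayes location/scale adjustment: standardize each
gene by its grand mean and pooled (within-batch-mean) variance, estimate
per-batch per-gene location γ̂ and scale δ̂², shrink them toward a normal
(moment-matched) and inverse-gamma (moment-matched) prior by iterating the
two conditional posterior modes to a joint fixed point, then subtract/divide
and restore the grand moments. No biological covariates are preserved —
the derivation supplies none. Verified against `sva::ComBat` (max
|difference| ≈ 3e-6 on a shared fixture, the EB iteration tolerance).
`shrink=False` gives the plain location/scale fit, which absorbs a pure
gene-wise offset exactly; with shrinkage a small residual is by design
(posterior means are pulled toward the batch consensus). One batch returns
the input unchanged; a batch with a single sample is an error because its
scale is inestimable.

Replicate averaging is the arithmetic mean on the log scale, one column
per (cell line, treatment), and precedes the gene-wise mean-centering
within each cell line. A single-column cell line centers to all zeros and
is flagged: its correlation with any signature is undefined.

## Signature derivation and scoring

Filters run sequentially: minimum expression (≥ 1 read in every profile
column) and then conservation ≥ 0.1. The conservation score
(correlation of correlations) uses Pearson correlations over the filtered
universe itself as the partner set, self-pairs excluded; it is symmetric in
its two datasets, and zero-variance genes are dropped with a warning.

Differential expression follows the moderated-t construction: pooled
two-sample variance s²_g on d_g = n − 2 df; hyperparameters (d₀, s₀²) by
the moment fit of a scaled F distribution on log variances (with the
trigamma-inverse Newton solve); posterior variance
s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g); p from t with d₀ + d_g df, BH-adjusted.
The implementation reproduces `limma::eBayes` to ~1e-14 on a frozen
fixture, including the degenerate branch: when the gene variances show no
excess spread, d₀ = ∞ and the prior scale is exp(mean e), which differs
from the common variance by the log-scale bias correction — the moderated
t then equals the ordinary t only up to a global constant.

"Most significant" means smallest moderated-t p within each fold-change
sign; ties break by larger |log2FC|, then lexicographic gene id, so the
selection is fully deterministic. Weights are the log2 fold changes.
Scoring is the Pearson correlation between the weight vector and a
profile's centered values over shared signature genes (≥ 3 required);
adding any gene-wise constant to the profiles does not change it.

## Enrichment test

The ranking statistic in phenotype mode is signal-to-noise with each class
sd floored at 0.2 × |class mean| (and a small absolute floor), as in the
reference desktop implementation. Hit increments are |stat|^w normalized
to unit mass (w = 1 default), misses subtract 1/(N − N_hit); ES is the
extremal running-sum deviation and the leading edge is the in-set genes at
or before the maximum (at or after the minimum for negative ES). Sample
permutation shuffles class labels; when the number of distinct splits is
at most `n_perm` the enumeration is exhaustive (logged). NES divides by
the mean same-sign permutation ES; nominal p is the same-sign permutation
tail with the +1 granularity floor 1/(P+1); FDR q is the pooled
normalized-score ratio, clipped to [0, 1]. A set with no same-sign
permutation scores gets NES = NA with a warning rather than ±∞. Classes
with fewer than 3 samples fall back to gene-permutation mode (random
same-size sets), recorded in the result.

## Limiting-dilution analysis

The exact single-hit likelihood is maximized over log f on [−30, 0]
(bounded Brent, xatol 1e-12); the 95% CI inverts the likelihood ratio at a
χ²₁(0.95)/2 = 1.9207 drop by root-finding on each side. All-responding
tables sit at the f = 1 boundary with a one-sided lower bound; all-negative
tables at the 0 boundary with a one-sided upper bound (both derived from
the same likelihood-ratio drop and flagged). The group comparison is the
LRT of a common frequency, χ² with (groups − 1) df; the two-arm fold change
carries a Wald CI on the log scale from the observed information
(central-difference second derivative in log f). A complementary log-log
binomial GLM with offset log(dose) — algebraically the same model — is
provided as a cross-check fitter. The LRT and frequencies were verified
against `statmod::elda` (identical χ² and p on shared tables). At the
in-vivo design emulated here (1/1000 vs 1/175, doses 10–10⁴, 12 wells per
dose) the expected LRT is ≈ 12.5, so a single experiment typically reaches
p ≈ 4e-4; p < 1e-4 occurs in a minority of replications, which bounds what
one such experiment can claim.

## Clinical statistics

Meta-analysis pools all ratio measures (HR/RR/OR) as-is on the log scale —
a deliberate simplification, flagged as a heterogeneity-of-measure caveat.
Missing standard errors are reconstructed in preference order CI → p:
SE = (log hi − log lo)/(2z₀.₉₇₅), else |log effect|/z(p); an effect of
exactly 1 with only a p is unrecoverable and errors. τ² maximizes the
restricted log-likelihood by bounded scalar optimization on
[0, max(10·var(y), 1e-4)] with xatol 1e-12 and a floor at 0 (truncated
REML) — same estimator as a scoring iteration, more robust near the
boundary; verified against `metafor::rma(method="REML")` to ~1e-6.
Heterogeneity is Cochran's Q at fixed-effect weights with
I² = max(0, (Q − df)/Q) (the classic Q-based definition; `metafor` prints
a τ²-based I², so that one field differs between the two).

Kaplan–Meier and the two-group log-rank (Mantel–Cox) test delegate to
lifelines. The Cox model is an in-package Newton–Raphson on the partial
likelihood with Breslow ties by default and Efron behind a flag (both
verified against statsmodels PHReg to ~1e-15); covariates are centered for
stability, constant covariates error, and coefficients diverging past |β| =
50 raise a monotone-likelihood (separation) diagnostic instead of silently
returning a huge hazard ratio. Exact normal quantiles are used throughout
(1.96 appears only in documentation arithmetic).

## Problem sizes in the shipped experiments

The canned experiments in `cmsshift.experiments` choose sizes that make
each property measurable while keeping a full battery cheap: signature
recovery on the 2000-gene / 100+100-sample cohort; shift detection on
800-gene / 40+40 cohorts with a 1-line, 2-arm, 6-replicate evaluation
experiment (one Bernoulli comparison per seed, so the null success rate is
exactly 1/2); dilution coverage on 100 seeds of the 4-dose × 12-well
ladder; meta recovery at k = 200 studies; survival recovery at 500 per
arm. The signature used for scoring is always derived from the 12-profile
study design at the observed shift (0.8): treated profiles with no
response carry no treatment-induced co-expression, so the conservation
filter would empty on null-only derivation data — the evaluation arms, not
the derivation set, carry the hypothesis being tested.

## Known limitations

- The conservation filter needs co-expression in the profile set; designs
  with a single cell line and no treatment response leave too few genes.
- The Cox model has no stratification, time-varying covariates, or robust
  variance; the log-rank test is two-group only.
- The enrichment FDR is the classic pooled-permutation estimate; no
  multilevel refinement of small p values.
- The meta-analysis module offers no publication-bias diagnostics or
  measure conversion; mixing HR/RR/OR is the caller's responsibility to
  interpret.
- Synthetic counts share one dispersion parameter across genes; real data
  show gene-dependent dispersion trends.
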