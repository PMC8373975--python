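# cms-shift

Tools for asking, computationally, whether a perturbation pushes epithelial
colorectal cancer cells toward a mesenchymal transcriptional state — the
CMS2 → CMS4 shift of the consensus molecular subtype (CMS) taxonomy — and
for the statistics that typically accompany such a study: gene-set
enrichment, limiting-dilution stem-cell frequencies, random-effects
meta-analysis, and survival models.

The motivating setting is adipose-tumor crosstalk: cancer-sphere cells
(CR-CSphCs) of the canonical CMS2 subtype exposed to conditioned medium
from visceral adipose stromal cells (V-ASC CM) acquire mesenchymal,
stem-like features. Because the underlying patient and sequencing data are
external, the package ships a first-class synthetic-data module that
generates every input with the statistical structure the analysis assumes
(planted differentially expressed genes, platform batch effects, single-hit
dilution assays, heterogeneous study effects, proportional hazards), so the
entire pipeline is testable offline against known ground truth.

## The core computation

1. **Reference cohort preparation.** Counts are normalized to reads per
   million and log2-transformed, `log2(1e6·c/total + 1)`. Two sequencing
   platforms are merged by a parametric empirical-Bayes location/scale
   batch adjustment (ComBat-family): per-gene standardized values get
   per-batch mean γ̂\_g and variance δ̂²\_g estimates shrunk toward
   normal / inverse-gamma priors, then the shrunken location is subtracted
   and the scale divided out.
2. **Gene filtering.** Candidate genes need at least one read in every
   cell-line profile, then a *correlation-of-correlations* conservation
   score ≥ 0.1: for gene g, the Pearson correlation — across partner genes —
   between g's co-expression vector in the reference cohort and in the
   cell-line profiles.
3. **Differential expression.** CMS4 vs CMS2 by empirical-Bayes moderated
   t: s̃²\_g = (d₀s₀² + d\_g s²\_g)/(d₀ + d\_g) with (d₀, s₀²) from a
   moment fit of a scaled F distribution to the gene variances;
   t̃\_g = log2FC\_g/(s̃\_g·c\_g) on d₀ + d\_g degrees of freedom
   (matches limma's `eBayes` to machine precision).
4. **Signature and score.** The signature is the log2 fold changes of the
   10 most significant up- and 10 most significant down-regulated genes. A
   profile's CMS4-ness is its Pearson correlation with those weights after
   averaging treatment replicates and mean-centering gene-wise within each
   cell line.

Around this sit: a weighted Kolmogorov–Smirnov gene-set enrichment test
with sample-permutation NES/p/FDR (Subramanian-style); an exact single-hit
limiting-dilution fitter, P(negative well) = (1−f)^dose, with
profile-likelihood CIs and a likelihood-ratio group comparison (agrees with
R `statmod::elda`); REML random-effects meta-analysis on the log-ratio
scale with the Altman reconstruction of missing standard errors from p
values (agrees with R `metafor`); Kaplan–Meier / log-rank via lifelines and
an in-package Newton–Raphson Cox model (Breslow or Efron ties); and the
bench formulas Q = P×I, V = d_max·d_min²·π/6, and 2^−ΔΔCt.

## Worked example

```python
import cmsshift as cs

cfg = cs.CohortConfig(n_genes=2000, n_samples_per_platform=(120, 80),
                      n_cms2=110, n_cms4=70, n_de_genes=100, seed=1)
counts, samples, truth = cs.simulate_reference_cohort(cfg)
adjusted, _ = cs.batch_adjust(cs.rpm_log2(counts), samples["platform"])

profiles, prof_ann = cs.simulate_cellline_profiles(cfg, truth, shift_fraction=0.8)
signature, stage_counts = cs.derive_signature(adjusted, samples["cms_label"], profiles)
print("stage counts:", stage_counts)

averaged, avg_ann = cs.average_replicates(cs.rpm_log2(profiles), prof_ann)
scores = cs.score_samples(signature, cs.center_within_group(averaged, avg_ann))
print(scores.round(3).to_string())
```

prints

```
stage counts: {'input_genes': 2000, 'min_expression': 2000, 'conserved': 143}
CL1_medium     -0.987
CL1_s_asc_cm    0.936
CL1_v_asc_cm    0.930
CL2_medium     -0.988
CL2_s_asc_cm    0.944
CL2_v_asc_cm    0.936
```

Both conditioned-medium arms of both cell lines correlate strongly
positively with the mesenchymal signature while their control arms sit at
the epithelial pole — the simulated analogue of the CM-induced CMS2 → CMS4
shift. A dilution assay comparison under the same seed:

```python
tbl = cs.simulate_lda([(1/175, (10, 100, 1000, 10_000), 12),
                       (1/1000, (10, 100, 1000, 10_000), 12)],
                      seed=1, labels=("V-ASC", "medium"))
```

fits `V-ASC: 1 in 235 (95% CI 1/114 – 1/485)`, `medium: 1 in 1410
(95% CI 1/723 – 1/2994)`, `fold change 6.01, LRT chi2 12.89, p = 3.30e-04`
— recovering the planted 5.71-fold enrichment of tumor-initiating cells
within its confidence interval.

The same stages are scriptable from the shell:

```sh
cms-shift run --simulate --outdir out --seed 1      # end-to-end synthetic study
cms-shift lda --table out/lda.csv --out lda.json
cms-shift meta --table out/meta.csv --out meta.json
```

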