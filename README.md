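# metamodule

Meta-gene co-expression analysis for predicting tumor recurrence from
bulk transcriptomics, built around the use case of meningioma — the most
common adult brain tumor, whose recurrence risk is still judged mostly
from histological (WHO) grade and extent of resection, with accuracy as
poor as a coin flip for low- and intermediate-grade cases.

The package implements the full analysis chain as a tested, reusable
library with an sklearn-style estimator surface and a CLI:

1. **Co-expression network & module discovery.** Gene–gene Pearson
   correlations are soft-thresholded, `a_ij = |cor(x_i, x_j)|^β`, with β
   the smallest natural number whose network approaches scale-free
   topology (log–log degree regression `r² ≥ 0.9`). The adjacency is
   converted to the topological overlap matrix

   `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   and `1 − TOM` is clustered by average-linkage with a two-stage hybrid
   adaptive tree cut (branch detection by size/coherence, then nearest-
   module assignment of stragglers).
2. **Meta-genes.** Each module is summarized per sample by the first
   principal component of its members' z-scored expression ("meta-gene",
   a.k.a. module eigengene), unit-variance and oriented to correlate
   positively with the module mean; `kME` is each gene's correlation
   with its module meta-gene. Module *gene lists* transfer across
   cohorts; meta-genes are recomputed within each cohort.
3. **Recurrence classifier.** Logistic regression on meta-genes,
   evaluated by stratified ten-fold cross-validation (PC1 loadings
   re-estimated inside every training fold — no held-out sample touches
   the PCA), by external transfer to validation cohorts, and within WHO
   grade strata. AUCs carry DeLong standard errors; paired curves are
   compared with DeLong's test. Multivariate models report the module's
   odds ratio controlling for WHO (and Simpson) grade.
4. **Sparsification.** Genes are removed from a module in descending
   order of individual AUC, the meta-gene recomputed after each removal,
   until the AUC falls below 90% of the full module (capped at 100
   removals); the removed genes form the "sparse module".
5. **Enrichment & TF markers.** Hypergeometric over-representation of
   module genes in GMT libraries with Benjamini–Hochberg q-values;
   transcription-factor markers require enrichment `q < 0.05` plus
   consistent differential expression (`t-test p < 0.05`) in every
   validation cohort.
6. **Synthetic cohorts.** A latent-factor generator plants co-expressed
   modules (`x_g = λ_g f_m + ε`), a logistic recurrence outcome on one
   module's factor, an ordered-logit WHO grade, log-normal
   time-to-recurrence and per-cohort batch effects — giving every stage
   a ground-truth test surface.

## Worked example

Simulate the default three-cohort study (discovery n=250 with planted
modules of 220 and 299 genes on a 912-gene panel, validation cohorts
n=110 and n=145 with batch shifts) and run the pipeline:

```python
from metamodule import AnalysisConfig, run_pipeline, simulate_multi_cohort
from metamodule.simulate import default_study_specs

specs = default_study_specs(seed=42)
(xd, phd, truth), v1, v2 = simulate_multi_cohort(specs)
report = run_pipeline((xd, phd), [v1[:2], v2[:2]], AnalysisConfig(seed=42))
```

This prints/reports (exact output of the run above):

```
module sizes: {'turquoise': 587, 'blue': 325}
predictive module: blue
recurrence t-test p = 3.41e-21, direction up
WHO-grade ANOVA p = 1.71e-13
TTR correlation rho = -0.92
10-fold CV AUC = 0.82 +/- 0.03
validation1: AUC = 0.82 +/- 0.04, module OR = 4.64 (p = 1.8e-05)
validation2: AUC = 0.86 +/- 0.03, module OR = 7.61 (p = 2.7e-08)
```

Reading: the tree cut finds two modules (named by size with the
conventional color sequence); the `blue` module's meta-gene is higher in
recurrent tumors (t-test), associates with WHO grade (ANOVA) and
correlates negatively with time to recurrence — the planted predictive
module, recovered from expression alone. Its classifier transfers to
both external cohorts with AUC ≈ the generative model's theoretical
ceiling (0.84), and the module stays significant when the logistic model
also controls for WHO grade.

The same stages are exposed as sklearn estimators
(`CoexpressionModules`, `MetageneTransformer`, `RecurrenceClassifier`,
`QuantileNormalizer`, `BatchCorrector`) that compose with sklearn model
selection, and as a CLI:

```bash
metamodule simulate --spec spec.yaml --out sim/
metamodule run --discovery sim/expression.tsv sim/phenotype.csv --seed 0 --out run/
```

## Layout

```
src/metamodule/
  io.py          containers + TSV/CSV/GMT/BED readers, run config
  simulate.py    synthetic multi-cohort generator + theoretical AUC oracle
  preprocess.py  log2, quantile normalization, cohort merge, batch correction
  network.py     adjacency, soft threshold, TOM, dendrogram, hybrid tree cut
  metagene.py    PC1 meta-genes, kME, cross-cohort projection
  association.py recurrence t-test, grade ANOVA, TTR correlation, TF screen,
                 gene linkage-distance correlation
  classify.py    logistic model, ROC/DeLong, CV, external/stratified eval
  sparsify.py    per-gene AUC ranking and iterative module sparsification
  enrichment.py  hypergeometric ORA with BH q-values
  pipeline.py    end-to-end orchestration;  cli.py  the `metamodule` CLI
```

See `docs/methods.md` for the model, parameter choices and limitations.
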