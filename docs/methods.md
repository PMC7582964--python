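# Methods

## The model

The package treats bulk expression as a noisy linear readout of a small
number of latent per-sample programs. A module `m` is a set of genes
whose expression is

    x_g = λ_g · f_m + ε,      ε ~ N(0, σ²),  λ_g ∈ (0, 1],

with `f_m` a standard-normal per-sample factor. Under this model the
first principal component of the module's z-scored expression is the
maximum-variance linear summary of the module and a consistent estimate
of `f_m`; that is the justification for the meta-gene construction, and
the synthetic-data generator is exactly this model so that the estimate
can be checked against the planted factor.

The clinical outcome is attached to one module's factor:

* recurrence: `y ~ Bernoulli(expit(β0 + β1 f))`,
* WHO grade: ordered logit, `P(grade ≤ j) = expit(c_j − γ f)`,
* time to recurrence (recurrent samples only):
  `t = exp(a − b f + η)`, `η ~ N(0, s²)`, truncated to the follow-up
  window — a decreasing function of the predictive factor chosen to
  produce the negative factor–TTR correlation without asserting any
  particular survival mechanism. Kaplan–Meier-style analysis is out of
  scope by design.

## Generator defaults (the study conditions)

The defaults emulate the discovery study design this pipeline is aimed
at: a 912-gene cancer panel carrying two planted modules of 220 and 299
genes (393 noise genes), discovery n = 250, validation cohorts n = 110
and n = 145 with additive per-gene batch shifts (sd 1–2) and a
multiplicative scale (1.3) standing in for a platform change.

* `β0 = −0.55` gives a ≈ 36% recurrence prevalence.
* `β1 = 1.75` gives a theoretical AUC of the true factor of 0.84
  (computed by the package's own 10⁶-draw Monte-Carlo oracle,
  `theoretical_auc`), in the range of published external-validation
  AUCs for this kind of classifier (≈ 0.77–0.87).
* grade cutpoints (0.2, 2.2) with slope 1.0 give ≈ 55/35/10% grade
  frequencies at `f = 0`.
* loadings `λ ~ U(0.6, 1)` and `σ = 0.6` give within-module gene–gene
  correlations of roughly 0.5–0.7, typical of tight co-expression
  modules; recovery tests use the cleaner regime `λ ≡ 1`, `σ = 0.4`.

These values were fixed from the study design, not tuned to test
outcomes. Batch shifts are additive/multiplicative per gene, which
leaves Pearson correlations (and hence module discovery and meta-genes)
untouched; their role is to exercise the merge/ComBat-style correction
path, not to degrade the classifier.

What the generator does **not** emulate: probe-level microarray physics
(saturation, background), count noise of RNA-seq (outputs are log-scale
continuous, as the pipeline consumes post-normalization data),
module–module correlation, and confounding between batch and outcome.
Passing tests therefore demonstrate correctness of the machinery under
a linear-factor world, not robustness to every failure mode of real
cross-platform data.

## Network construction and module detection

Adjacency is unsigned by default, `a = |cor|^β` (signed mode
`((1+cor)/2)^β` is available); unsigned is the historical default for
this family of methods and the natural reading of "correlations raised
to a power". The soft-threshold power is the smallest natural number
whose degree distribution fits a power law with `r² ≥ 0.9` and negative
slope. The fit bins log-connectivity into 10 equal-count bins and
regresses the log *density* (count divided by bin width) on the bin
mean — with equal-count bins the raw frequency is constant by
construction, while the density keeps a power law exactly log–log
linear. When no candidate reaches the target the best candidate is
returned *flagged*, never silently: strongly modular data (including
the synthetic cohorts) are typically not scale-free, and the flag is
informative, not fatal — module detection is robust to the power in the
regimes tested.

TOM is computed with the standard shared-neighbor formula and
`1 − TOM` clustered with scipy's average linkage. The hybrid tree cut
is a two-stage procedure in the spirit of the dynamic hybrid method:

1. Static cuts of the dendrogram are scanned (up to 60 quantile levels
   of the merge heights, capped at `max_height` × top merge). At each
   cut a branch qualifies as a module if, after stripping incoherent
   members, at least `min_size` genes remain. A member is stripped when
   its mean dissimilarity to the branch exceeds a ceiling interpolated
   from `deep_split` (0.64…0.95 on the normalized dissimilarity scale —
   this kills branches made of mutually distant noise genes), or when it
   sits closer to the branch's exterior than to its core (mean member
   dissimilarity > core median + ½·(exterior − core) — this strips
   noise genes chained onto a real branch). The cut with the most
   qualifying branches wins; ties go to the cut assigning more genes,
   so each branch is taken as high as coherence allows.
2. With `pam_stage` on (default), every leftover gene is assigned to
   the module of smallest average dissimilarity — mirroring the
   observation that on a targeted cancer panel essentially every gene
   joins a module. With it off, noise genes stay `unassigned`.

Both stages are deterministic. Modules are ordered by size and named by
the conventional color sequence (turquoise, blue, …).

## Meta-genes and cross-cohort transfer

Member genes are z-scored per gene; the meta-gene is the first right
singular vector scaled to unit variance, sign-fixed so it correlates
non-negatively with the module's mean standardized expression. Only
gene lists transfer across cohorts; PC1 is recomputed within each
cohort (the orientation rule keeps signs comparable). The alternative —
projecting discovery loadings — is available through
`MetageneTransformer`, which is also what strict cross-validation uses
inside folds.

## Classification and inference

The logistic model is unpenalized maximum likelihood (statsmodels) with
Wald CIs; complete separation and non-convergence are detected and
flagged on the returned model rather than raised. Meta-genes are unit
variance, so module odds ratios are per-SD of meta-gene; cohorts or
models with near-separable strata can produce very large ORs, which the
separation flag accompanies.

Cross-validation is stratified k-fold (seeded; ties broken by the
shuffle). In the default *strict* mode, per-module standardization
parameters and PC1 loadings are estimated on the training folds only
and held-out samples are projected — an adversarial test in the suite
plants outcome signal along fold-specific orthogonal gene directions
and verifies strict CV stays at chance while the *whole-cohort*
compatibility mode (meta-genes computed once on all samples) leaks.
When a class has fewer members than folds, the partition falls back to
unstratified with a warning (leave-one-out remains possible).

AUC is the Mann–Whitney statistic with half credit for ties; its
standard error and the paired curve comparison use DeLong's structural
components (placement values via midranks). The "AUC ± x" notation in
reports is the DeLong SE. Per-grade performance uses whole-cohort
meta-genes and a full-cohort fit, subsetting only the evaluation.

## Sparsification

The ranking is static (individual AUCs computed once, direction-folded
`max(AUC, 1−AUC)` since members may anti-correlate with the meta-gene);
re-ranking after each removal is available behind a flag, as is
unfolded reporting. The sparse set includes the removal that crosses
the 90% boundary (inclusive reading; exclusive is a flag). A module
whose full meta-gene AUC is ≤ 0.5 is rejected as "not predictive"
rather than sparsified.

A note on the z-scored PC1: once only a single outcome-linked gene
remains among otherwise uncorrelated filler, PC1 gives it no weight, so
the meta-gene loses that signal at the removal *before* the last signal
gene unless the signal genes stay coupled to the module through a
shared non-outcome factor. The test construction for "exactly the
planted signal genes are returned" uses such coupling in a weak-signal
regime; this is a real property of eigengene-based sparsification, not
an implementation artifact.

## Preprocessing

Quantile normalization maps every sample onto the vector of per-rank
cross-sample means, ties receiving the mean of the reference values
over their tied ranks. Batch correction defaults to the parametric
empirical-Bayes location/scale model (per-gene batch effects shrunk
toward across-gene priors, normal for locations and inverse-gamma for
scales, solved by the standard fixed-point iteration) with a
transparent location-scale fallback that aligns per-gene batch moments
exactly. EB shrinkage deliberately leaves per-gene sampling residue in
exchange for lower estimator MSE — verified by a Monte-Carlo comparison
in the suite. The stage order `log2 → quantile → merge → batch` is
recorded in the matrix's provenance and enforced; a per-array
median-scale step is available for legacy platforms but not in the
default chain. Cohorts are quantile-normalized before merging, then
batch-corrected (the order is a declared choice).

## Numerical and degenerate-input choices

* Welch's t-test by default (pooled-variance behind `equal_var=True`);
  identical degenerate groups return `p = 1` by convention.
* TTR correlation defaults to year-binned means (bins with ≥ 3
  samples), matching the magnitude of published binned correlations;
  per-sample mode is a flag.
* Duplicate gene rows collapse by maximum variance (mean available);
  duplicate sample ids across merged cohorts are suffixed with the
  batch label.
* Zero-variance genes are dropped from correlation/PCA steps with a
  logged count, or rejected where silence would be misleading.
* Enrichment universe defaults to the genes on the platform, material
  for targeted panels; gene symbols match case-insensitively.
* All randomness (simulation, fold assignment, permutation tests) flows
  from explicit seeds; identical seeds give bit-identical outputs.

## Problem sizes used in the test suite

Oracle-equivalence tests run on thousands of small random instances
(n ≤ 50 samples, ≤ 12 genes for the TOM brute force). Recovery and
calibration tests use the regimes stated above (n = 150–2000, 20 seeds
for module recovery, 500 replicates for logistic coverage, 1000
simulations for DeLong calibration). The end-to-end replication runs
the full 912-gene, three-cohort study over 10 seeds. These sizes make
the whole suite complete in a couple of minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances — except
where a tolerance is deliberately tighter than sampling noise allows
(see the external-AUC discussion below).

## Known limitations

* The hybrid tree cut implements the core branch-coherence/PAM logic,
  not every refinement of the reference dynamic-hybrid implementation;
  on deeply nested module hierarchies the static-cut scan can merge
  adjacent sub-modules that the full algorithm would split.
* The scale-free flag is advisory; on targeted panels (few hundred
  correlated genes) the degree distribution rarely fits a power law
  and the selected power falls back to the best candidate.
* External validation AUCs at n ≈ 110–145 carry sampling SEs of
  0.035–0.045; point estimates should be read with their DeLong SEs,
  and any fixed ±0.05 band around a target will fail a noticeable
  fraction of honest runs at these sizes.
* ComBat-style correction here carries no outcome covariates; it is
  applied before and independently of modeling, and would attenuate
  real signal if batch were confounded with outcome.
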