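"""Synthetic multi-cohort expression data with planted module structure.

The generative model mirrors the latent-factor view implicit in PC1
meta-gene summarization: each planted module m has a per-sample latent
factor f_m ~ N(0,1), and a member gene g has expression

    x_g = lambda_g * f_m + eps,    eps ~ N(0, sigma^2)

with noise genes pure eps.  One module (the first, by convention) drives
the clinical phenotype: recurrence ~ Bernoulli(expit(beta0 + beta1*f)),
WHO grade by an ordered logit on the same factor, and time-to-recurrence
log-normally decreasing in the factor.  Cohort (batch) effects are
additive per-gene shifts plus a multiplicative scale.

Defaults emulate the discovery study conditions: n = 250 samples, two
planted modules of 220 and 299 genes on a 912-gene cancer panel
(393 noise genes), ~36% recurrence prevalence and WHO grade frequencies
of roughly 55/35/10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .io import ExpressionMatrix, PhenotypeTable, ValidationError


@dataclass
class SyntheticCohortSpec:
    """Parameters of one simulated cohort.

    The first module listed in ``module_sizes`` is the outcome-linked
    ("predictive") module.  ``loading_range`` bounds the per-gene factor
    loadings lambda (drawn uniformly); set both ends to 1 for the exact
    rank-one regime.  ``beta0``/``beta1`` are the intercept and slope of
    the logistic recurrence model on the predictive factor.
    """

    n_samples: int = 250
    module_sizes: Sequence[int] = (220, 299)
    n_noise_genes: int = 393
    loading_range: tuple = (0.6, 1.0)
    sigma: float = 0.6
    beta0: float = -0.55
    beta1: float = 1.75
    grade_slope: float = 1.0
    grade_cutpoints: tuple = (0.2, 2.2)
    ttr_log_intercept: float = 1.1
    ttr_log_slope: float = 0.5
    ttr_log_sd: float = 0.4
    followup_max: float = 15.0
    batch_label: str = "cohort0"
    batch_shift_sd: float = 0.0
    batch_scale: float = 1.0
    seed: int = 0
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if any(m < 2 for m in self.module_sizes):
            raise ValidationError("module sizes must be >= 2")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("loadings must lie in (0, 1]")
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        if self.n_noise_genes < 0:
            raise ValidationError("n_noise_genes must be >= 0")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_noise_genes

    def gene_ids(self) -> list:
        return [f"{self.gene_prefix}{i:04d}" for i in range(self.n_genes)]

    def true_labels(self) -> pd.Series:
        """Ground-truth gene -> module label ('noise' for noise genes)."""
        labels = []
        for m, size in enumerate(self.module_sizes):
            labels += [f"module{m}"] * size
        labels += ["noise"] * self.n_noise_genes
        return pd.Series(labels, index=self.gene_ids(), name="true_module")


@dataclass
class SyntheticTruth:
    """Planted quantities for parameter-recovery tests."""

    factors: pd.DataFrame          # samples x modules latent factors
    gene_labels: pd.Series         # gene -> module / 'noise'
    loadings: pd.Series            # gene -> lambda (0 for noise genes)
    beta0: float
    beta1: float
    batch_label: str

    def predictive_factor(self) -> pd.Series:
        return self.factors["module0"]

    def to_json_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "batch": self.batch_label,
            "gene_labels": self.gene_labels.to_dict(),
            "factors": {c: self.factors[c].tolist() for c in self.factors},
            "sample_ids": list(self.factors.index),
        }


def simulate_cohort(spec: SyntheticCohortSpec):
    """Draw one cohort; returns (ExpressionMatrix, PhenotypeTable, SyntheticTruth).

    The same seed yields bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, len(spec.module_sizes)
    sample_ids = [f"{spec.batch_label}_s{i:04d}" for i in range(n)]
    gene_ids = spec.gene_ids()
    labels = spec.true_labels()

    factors = rng.standard_normal((n, k))
    lo, hi = spec.loading_range
    lam = np.zeros(spec.n_genes)
    rows = np.zeros((spec.n_genes, n))
    start = 0
    for m, size in enumerate(spec.module_sizes):
        lam_m = rng.uniform(lo, hi, size) if hi > lo else np.full(size, hi)
        lam[start:start + size] = lam_m
        rows[start:start + size] = lam_m[:, None] * factors[:, m][None, :]
        start += size
    rows += rng.normal(0.0, spec.sigma, rows.shape)

    # batch effect: per-gene additive shift, global multiplicative scale
    if spec.batch_shift_sd > 0 or spec.batch_scale != 1.0:
        shifts = rng.normal(0.0, spec.batch_shift_sd, spec.n_genes) \
            if spec.batch_shift_sd > 0 else np.zeros(spec.n_genes)
        rows = rows * spec.batch_scale + shifts[:, None]

    f_pred = factors[:, 0]
    p_rec = expit(spec.beta0 + spec.beta1 * f_pred)
    recurrence = (rng.uniform(size=n) < p_rec).astype(int)

    # ordered logit for WHO grade: P(grade<=j) = expit(c_j - slope*f)
    c1, c2 = spec.grade_cutpoints
    u = rng.uniform(size=n)
    p1 = expit(c1 - spec.grade_slope * f_pred)
    p2 = expit(c2 - spec.grade_slope * f_pred)
    grade = np.where(u < p1, 1, np.where(u < p2, 2, 3))

    simpson = rng.integers(1, 6, size=n).astype(float)

    ttr = np.full(n, np.nan)
    rec_mask = recurrence == 1
    n_rec = int(rec_mask.sum())
    raw_ttr = np.exp(
        spec.ttr_log_intercept
        - spec.ttr_log_slope * f_pred[rec_mask]
        + rng.normal(0.0, spec.ttr_log_sd, n_rec)
    )
    ttr[rec_mask] = np.clip(raw_ttr, 0.25, spec.followup_max)

    follow_up = rng.uniform(1.0, spec.followup_max, n)
    follow_up[rec_mask] = np.maximum(follow_up[rec_mask], ttr[rec_mask])

    x = ExpressionMatrix(pd.DataFrame(rows, index=gene_ids, columns=sample_ids))
    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": sample_ids,
        "recurrence": recurrence,
        "who_grade": grade,
        "simpson_grade": simpson,
        "time_to_recurrence": ttr,
        "follow_up": follow_up,
        "batch": spec.batch_label,
    }))
    truth = SyntheticTruth(
        factors=pd.DataFrame(factors, index=sample_ids,
                             columns=[f"module{m}" for m in range(k)]),
        gene_labels=labels,
        loadings=pd.Series(lam, index=gene_ids, name="loading"),
        beta0=spec.beta0,
        beta1=spec.beta1,
        batch_label=spec.batch_label,
    )
    return x, pheno, truth


def simulate_multi_cohort(specs: Sequence[SyntheticCohortSpec]):
    """Draw several cohorts sharing the gene universe and module truth.

    Cohorts differ in sample draws, sizes and batch offsets; module
    definitions (sizes, ordering, loading ranges) must agree.
    """
    if len(specs) < 2:
        raise ValidationError("need at least 2 cohort specs")
    ref = specs[0]
    for s in specs[1:]:
        if tuple(s.module_sizes) != tuple(ref.module_sizes) \
                or s.n_noise_genes != ref.n_noise_genes \
                or s.gene_prefix != ref.gene_prefix:
            raise ValidationError("cohort specs must share the gene universe")
    labels = {s.batch_label for s in specs}
    if len(labels) < len(specs):
        raise ValidationError("cohort batch labels must be distinct")
    return [simulate_cohort(s) for s in specs]


def default_study_specs(seed: int = 0):
    """The three-cohort synthetic study design: one discovery cohort
    (n=250) and two validation cohorts (n=110 and n=145, the second with
    a batch shift emulating a platform change)."""
    base = SyntheticCohortSpec(seed=seed)
    return [
        replace(base, n_samples=250, batch_label="discovery", seed=seed),
        replace(base, n_samples=110, batch_label="validation1",
                batch_shift_sd=1.0, seed=seed + 1),
        replace(base, n_samples=145, batch_label="validation2",
                batch_shift_sd=2.0, batch_scale=1.3, seed=seed + 2),
    ]


def theoretical_auc(spec: SyntheticCohortSpec, n_draws: int = 1_000_000,
                    seed: int = 12345) -> float:
    """Monte-Carlo AUC of the true latent factor for recurrence.

    Draws f ~ N(0,1), y ~ Bernoulli(expit(beta0 + beta1 f)) and computes
    the Mann-Whitney AUC of f as a predictor of y.  This is the ceiling
    any meta-gene-based classifier can reach under the spec's model.
    """
    if not np.isfinite(spec.beta1):
        raise ValidationError("beta1 must be finite")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_draws)
    y = rng.uniform(size=n_draws) < expit(spec.beta0 + spec.beta1 * f)
    n_pos = int(y.sum())
    n_neg = n_draws - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(f)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
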