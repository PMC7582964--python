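"""Normalization and cohort merging.

The canonical chain is ``log2 -> quantile -> merge -> batch_correct``;
each stage records itself in the matrix's provenance and refuses to run
after a later stage has already been applied.  Batch correction offers a
transparent location-scale mode and an empirical-Bayes mode that shrinks
per-gene batch parameters toward across-gene priors (the parametric
ComBat model, without outcome covariates since correction precedes and
is independent of outcome modeling).

Sklearn-compatible transformers (:class:`QuantileNormalizer`,
:class:`BatchCorrector`) operate on (samples x genes) arrays; the
module-level functions wrap them for :class:`ExpressionMatrix` inputs
(genes x samples).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("log2", "quantile", "merge", "batch")


def _check_stage(x: ExpressionMatrix, stage: str) -> None:
    later = _STAGE_ORDER[_STAGE_ORDER.index(stage) + 1:]
    applied = [s for s in x.stages if s in later]
    if applied:
        raise ValidationError(
            f"stage {stage!r} cannot run after {applied}: pipeline order is "
            + " -> ".join(_STAGE_ORDER)
        )


# ---------------------------------------------------------------------------
# core numerics (genes x samples arrays)
# ---------------------------------------------------------------------------

def _quantile_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns against the per-rank cross-column mean.

    Ties within a column receive the mean of the reference values over
    their tied ranks.
    """
    g, n = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    # cumulative sums give tied-rank means in O(g log g) per column
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(n):
        col = values[:, j]
        r = rankdata(col, method="average")        # average rank, 1-based
        rmin = rankdata(col, method="min").astype(int)
        rmax = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
        del r
    return out


def _map_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Assign each column the (tie-averaged) reference quantiles."""
    g = values.shape[0]
    if len(reference) != g:
        # interpolate the stored reference onto this gene count
        src = np.linspace(0, 1, len(reference))
        dst = np.linspace(0, 1, g)
        reference = np.interp(dst, src, reference)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        rmin = rankdata(col, method="min").astype(int)
        rmax = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return out


def _location_scale_correct(values: np.ndarray, batch_codes: np.ndarray):
    """Align each batch's per-gene mean/variance to the pooled ones."""
    out = values.astype(float).copy()
    pooled_mean = values.mean(axis=1)
    pooled_sd = values.std(axis=1, ddof=1)
    n_skipped = 0
    for b in np.unique(batch_codes):
        cols = batch_codes == b
        sub = values[:, cols]
        bmean = sub.mean(axis=1)
        bsd = sub.std(axis=1, ddof=1)
        ok = bsd > 0
        n_skipped += int((~ok).sum())
        scale = np.where(ok, pooled_sd / np.where(ok, bsd, 1.0), 1.0)
        out[:, cols] = (sub - bmean[:, None]) * scale[:, None] + pooled_mean[:, None]
    if n_skipped:
        logger.info("scale step skipped for %d zero-variance gene/batch pairs",
                    n_skipped)
    return out


def _eb_batch_correct(values: np.ndarray, batch_codes: np.ndarray,
                      max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Parametric empirical-Bayes batch adjustment (ComBat model).

    Per-gene batch location/scale estimates are shrunk toward across-gene
    priors (normal for locations, inverse-gamma for scales) before the
    adjustment is applied on standardized data.
    """
    g, n = values.shape
    batches = np.unique(batch_codes)
    n_b = np.array([(batch_codes == b).sum() for b in batches], dtype=float)

    # gene-wise grand mean and pooled variance under the batch-means model
    batch_means = np.column_stack([
        values[:, batch_codes == b].mean(axis=1) for b in batches
    ])
    grand_mean = batch_means @ (n_b / n)
    resid = values - batch_means[:, np.searchsorted(batches, batch_codes)]
    pooled_var = (resid ** 2).sum(axis=1) / n
    pooled_var = np.where(pooled_var > 0, pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)

    z = (values - grand_mean[:, None]) / sd[:, None]

    adjusted = z.copy()
    for bi, b in enumerate(batches):
        cols = batch_codes == b
        nb = int(n_b[bi])
        zb = z[:, cols]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1) if nb > 1 else np.ones(g)
        delta_hat = np.where(delta_hat > 0, delta_hat, 1e-12)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        v = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if s2 <= 0 or tau2 <= 0:
            gamma_star, delta_star = gamma_hat, delta_hat
        else:
            lam = (v ** 2 + 2 * s2) / s2
            theta = (v ** 3 + v * s2) / s2
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) \
                    / (nb * tau2 + delta_star)
                sse = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * sse) / (nb / 2.0 + lam - 1.0)
                change = max(np.abs(g_new - gamma_star).max(),
                             np.abs(d_new - delta_star).max())
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
        adjusted[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    return adjusted * sd[:, None] + grand_mean[:, None]


def estimate_batch_shifts(values: np.ndarray, batch_codes: np.ndarray,
                          mode: str = "eb-shrinkage") -> np.ndarray:
    """Per-gene location-shift estimates for the *last* batch relative to
    the grand mean, on the standardized scale times sd (expression units).

    Exposed for benchmarking shrinkage against raw per-gene estimates.
    """
    g, n = values.shape
    batches = np.unique(batch_codes)
    grand = values.mean(axis=1)
    b = batches[-1]
    raw = values[:, batch_codes == b].mean(axis=1) - grand
    if mode == "location-scale":
        return raw
    # EB shrinkage of the location estimates toward their across-gene mean
    nb = (batch_codes == b).sum()
    within_var = np.mean([values[:, batch_codes == bb].var(axis=1, ddof=1)
                          for bb in batches], axis=0)
    tau2 = max(raw.var(ddof=1) - within_var.mean() / nb, 1e-12)
    w = tau2 / (tau2 + within_var / nb)
    return raw.mean() + w * (raw - raw.mean())


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------

class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force every sample (row) to share one empirical distribution.

    ``fit`` learns the reference distribution — the vector of per-rank
    means across the fitted samples; ``transform`` reassigns each row's
    values to those reference quantiles, averaging over ties.  Input
    follows the sklearn convention (n_samples, n_features).
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return _map_to_reference(X.T, self.reference_distribution_).T


class BatchCorrector(BaseEstimator, TransformerMixin):
    """Remove per-batch location/scale effects from (samples x genes) data.

    mode="eb-shrinkage" (default) applies the parametric empirical-Bayes
    adjustment; mode="location-scale" aligns each batch's per-gene moments
    to the pooled ones directly.  ``fit_transform(X, batches=...)`` is the
    intended entry point: the correction is defined jointly on the data it
    is given.
    """

    def __init__(self, mode: str = "eb-shrinkage"):
        self.mode = mode

    def fit(self, X, y=None, *, batches=None):
        X = check_array(X)
        if batches is None:
            raise ValidationError("BatchCorrector.fit requires batches=")
        batches = np.asarray(batches)
        if len(batches) != X.shape[0]:
            raise ValidationError("batches length must match n_samples")
        uniq, counts = np.unique(batches, return_counts=True)
        if len(uniq) < 2:
            raise ValidationError("need >= 2 batches")
        if counts.min() < 2:
            small = uniq[counts < 2].tolist()
            raise ValidationError(f"batches with a single sample: {small}")
        if self.mode not in ("eb-shrinkage", "location-scale"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        self.batches_ = batches
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[0] != len(self.batches_):
            raise ValidationError("transform expects the fitted samples")
        vals = X.T  # genes x samples
        if self.mode == "location-scale":
            out = _location_scale_correct(vals, self.batches_)
        else:
            out = _eb_batch_correct(vals, self.batches_)
        return out.T


# ---------------------------------------------------------------------------
# ExpressionMatrix-level operations
# ---------------------------------------------------------------------------

def log2_transform(x: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); input must be linear-scale."""
    _check_stage(x, "log2")
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    vals = x.values + offset
    if (vals <= 0).any():
        bad = np.argwhere(vals <= 0)
        coords = [(x.gene_ids[i], x.sample_ids[j]) for i, j in bad[:5]]
        raise ValidationError(
            f"non-positive values after offset {offset}: {coords}"
            + (f" and {len(bad) - 5} more" if len(bad) > 5 else "")
        )
    out = ExpressionMatrix(pd.DataFrame(np.log2(vals), index=x.gene_ids,
                                        columns=x.sample_ids), stages=x.stages)
    return out.with_stage("log2")


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Give every sample the identical sorted value vector (rank means)."""
    _check_stage(x, "quantile")
    if x.n_samples == 1:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return x.with_stage("quantile")
    vals = _quantile_normalize_columns(x.values)
    out = ExpressionMatrix(pd.DataFrame(vals, index=x.gene_ids,
                                        columns=x.sample_ids), stages=x.stages)
    return out.with_stage("quantile")


def merge_cohorts(xs: Sequence[ExpressionMatrix],
                  batches: Optional[Sequence[str]] = None) -> ExpressionMatrix:
    """Concatenate cohorts on the intersection of their gene universes."""
    if len(xs) == 0:
        raise ValidationError("no cohorts to merge")
    for x in xs:
        _check_stage(x, "merge")
    if batches is None:
        batches = [f"batch{i}" for i in range(len(xs))]
    if len(batches) != len(xs):
        raise ValidationError("one batch label per cohort required")
    if len(xs) == 1:
        return xs[0]
    common = xs[0].data.index
    for x in xs[1:]:
        common = common.intersection(x.data.index)
    if len(common) == 0:
        raise ValidationError("empty gene intersection across cohorts")
    common = [g for g in xs[0].gene_ids if g in set(common)]

    frames = []
    seen = set()
    for x, b in zip(xs, batches):
        df = x.data.loc[common]
        rename = {}
        for s in df.columns:
            if s in seen:
                rename[s] = f"{s}.{b}"
        if rename:
            logger.info("merge_cohorts: %d duplicate sample ids suffixed with "
                        "batch %r", len(rename), b)
            df = df.rename(columns=rename)
        seen.update(df.columns)
        frames.append(df)
    merged = pd.concat(frames, axis=1)
    stages = tuple(s for s in xs[0].stages if all(s in x.stages for x in xs))
    return ExpressionMatrix(merged, stages=stages).with_stage("merge")


def batch_correct(x: ExpressionMatrix, batches: Sequence[str],
                  mode: str = "eb-shrinkage") -> ExpressionMatrix:
    """Remove per-cohort batch effects (see :class:`BatchCorrector`)."""
    _check_stage(x, "batch")
    if len(batches) != x.n_samples:
        raise ValidationError("one batch label per sample required")
    corrector = BatchCorrector(mode=mode)
    out_vals = corrector.fit_transform(x.values.T, batches=np.asarray(batches)).T
    out = ExpressionMatrix(pd.DataFrame(out_vals, index=x.gene_ids,
                                        columns=x.sample_ids), stages=x.stages)
    return out.with_stage("batch")


def median_scale(x: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its 50th-percentile value (per-array median
    scaling, as used by some legacy platforms).  Linear-scale inputs."""
    med = np.median(x.values, axis=0)
    if (med == 0).any():
        raise ValidationError("zero median sample; cannot median-scale")
    vals = x.values / med[None, :]
    return ExpressionMatrix(pd.DataFrame(vals, index=x.gene_ids,
                                         columns=x.sample_ids), stages=x.stages)
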