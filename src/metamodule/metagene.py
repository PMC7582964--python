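"""First-principal-component meta-genes and module membership (kME).

A module's meta-gene is the first principal component of its members'
per-gene standardized expression, scaled to unit variance across samples
and oriented so it correlates non-negatively with the module's mean
standardized expression.  Meta-genes are recomputed within each cohort;
only gene lists transfer across cohorts (the orientation rule keeps the
signs comparable).

:class:`MetageneTransformer` is the sklearn-compatible face: ``fit``
learns per-module standardization and PC1 loadings on training samples
and ``transform`` projects any cohort's samples onto them — the strict
form used inside cross-validation to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, ValidationError
from .network import ModulePartition

logger = logging.getLogger(__name__)


@dataclass
class MetageneMatrix:
    """Module x sample meta-gene scores with per-module variance explained."""

    scores: pd.DataFrame            # modules x samples, unit variance rows
    variance_explained: dict        # module -> fraction of module variance

    @property
    def module_names(self) -> list:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list:
        return list(self.scores.columns)

    def series(self, module: str) -> pd.Series:
        return self.scores.loc[module]

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _module_pc1(values: np.ndarray):
    """(loadings w, scores, variance_explained) for standardized rows.

    ``scores = w @ values_std`` has unit variance; reapplying ``w`` to
    standardized held-out samples projects them onto the same axis.
    """
    m, n = values.shape
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    std = (values - mean[:, None]) / sd[:, None]
    u, s, vt = np.linalg.svd(std, full_matrices=False)
    score_raw = s[0] * vt[0]                      # PC1 sample scores
    scale = score_raw.std(ddof=1)
    if scale == 0:
        raise ValidationError("degenerate module: PC1 has zero variance")
    w = u[:, 0] / scale                           # so that w @ std = scores
    scores = score_raw / scale
    # orientation: positive correlation with the module mean profile
    mean_profile = std.mean(axis=0)
    if np.dot(scores - scores.mean(), mean_profile - mean_profile.mean()) < 0:
        w, scores = -w, -scores
    var_exp = float(s[0] ** 2 / (s ** 2).sum())
    return mean, sd, w, scores, var_exp


def _usable_module_genes(x: ExpressionMatrix, genes: Sequence) -> list:
    present = [g for g in genes if g in x.data.index]
    n_absent = len(genes) - len(present)
    if n_absent:
        logger.info("%d module genes absent from cohort, dropped", n_absent)
    vals = x.data.loc[present].to_numpy()
    sd = vals.std(axis=1, ddof=1)
    flat = [g for g, s in zip(present, sd) if s == 0]
    if flat:
        logger.info("%d zero-variance module genes dropped from PCA", len(flat))
        present = [g for g in present if g not in set(flat)]
    if len(present) < 2:
        raise ValidationError(
            f"module reduced to {len(present)} usable genes (< 2)")
    return present


class MetageneTransformer(BaseEstimator, TransformerMixin):
    """Project samples onto per-module PC1 axes learned at fit time.

    Parameters
    ----------
    modules : mapping of module name -> gene id list
        Module definitions (gene lists transfer between cohorts).

    ``fit(X)`` expects a (samples x genes) DataFrame; ``transform``
    returns a (samples x modules) DataFrame of meta-gene scores on the
    training scale.
    """

    def __init__(self, modules: Mapping[str, Sequence] = None):
        self.modules = modules

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("MetageneTransformer requires a DataFrame "
                                  "with gene-id columns")
        if not self.modules:
            raise ValidationError("no module gene lists supplied")
        xm = ExpressionMatrix(X.T)
        self.loadings_ = {}
        self.variance_explained_ = {}
        for name, genes in self.modules.items():
            usable = _usable_module_genes(xm, genes)
            mean, sd, w, _, var_exp = _module_pc1(xm.data.loc[usable].to_numpy())
            self.loadings_[name] = (usable, mean, sd, w)
            self.variance_explained_[name] = var_exp
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("MetageneTransformer requires a DataFrame")
        cols = {}
        for name, (genes, mean, sd, w) in self.loadings_.items():
            missing = [g for g in genes if g not in X.columns]
            if missing:
                raise ValidationError(
                    f"module {name}: {len(missing)} fitted genes missing")
            vals = X[genes].to_numpy().T
            std = (vals - mean[:, None]) / sd[:, None]
            cols[name] = w @ std
        return pd.DataFrame(cols, index=X.index)


def compute_metagenes(x: ExpressionMatrix,
                      partition_or_modules) -> MetageneMatrix:
    """Meta-gene scores recomputed within the cohort ``x``.

    ``partition_or_modules`` is a :class:`ModulePartition` or a mapping
    module name -> gene list.  Each named module must retain >= 2 usable
    genes in ``x``.
    """
    if isinstance(partition_or_modules, ModulePartition):
        modules = partition_or_modules.modules()
    else:
        modules = dict(partition_or_modules)
    if not modules:
        raise ValidationError("no modules to summarize")
    scores = {}
    var_exp = {}
    for name, genes in modules.items():
        usable = _usable_module_genes(x, genes)
        _, _, _, s, ve = _module_pc1(x.data.loc[usable].to_numpy())
        scores[name] = s
        var_exp[name] = ve
    mat = pd.DataFrame(scores, index=x.sample_ids).T
    return MetageneMatrix(scores=mat, variance_explained=var_exp)


def compute_kme(x: ExpressionMatrix, mg: MetageneMatrix) -> pd.DataFrame:
    """Pearson correlation of each gene with each module meta-gene."""
    shared = [s for s in x.sample_ids if s in set(mg.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared samples")
    vals = x.data[shared].to_numpy()
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.info("kME missing for %d zero-variance genes", int(flat.sum()))
    out = {}
    vc = vals - vals.mean(axis=1, keepdims=True)
    vnorm = np.sqrt((vc ** 2).sum(axis=1))
    for name in mg.module_names:
        m = mg.scores.loc[name, shared].to_numpy()
        mc = m - m.mean()
        denom = vnorm * np.sqrt((mc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, vc @ mc / denom, np.nan)
        out[name] = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(out, index=x.gene_ids)
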