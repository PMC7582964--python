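"""Weighted gene co-expression network construction and module detection.

The chain is the classic WGCNA recipe: gene-gene Pearson correlations,
soft-thresholding by a power chosen for approximate scale-free topology,
conversion to the topological overlap matrix (TOM), average-linkage
hierarchical clustering of the TOM dissimilarity, and a two-stage hybrid
adaptive tree cut.  :class:`CoexpressionModules` packages the chain as an
sklearn-style feature-clustering estimator (cf. FeatureAgglomeration:
``fit`` takes samples x genes and ``labels_`` indexes genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

#: module label sequence, largest module first (grey is reserved for
#: unassigned genes, matching the field's convention)
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

UNASSIGNED = "unassigned"

# branch-coherence ceiling per deep_split level (0..4); a candidate branch
# whose normalized mean internal dissimilarity exceeds this is not a module
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded co-expression adjacency: symmetric, unit diagonal,
    entries in [0, 1]."""

    gene_ids: list
    values: np.ndarray
    power: int
    sign_mode: str = "unsigned"

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.gene_ids):
            raise ValidationError("adjacency shape inconsistent with gene ids")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValidationError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValidationError("adjacency entries must lie in [0,1]")
        np.fill_diagonal(a, 1.0)
        self.values = np.clip(a, 0.0, 1.0)

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum_{j != i} a_ij."""
        return self.values.sum(axis=1) - 1.0


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit for one candidate power."""

    power: int
    r2: float
    slope: float
    mean_connectivity: float


@dataclass
class TOMatrix:
    """Topological overlap: similarity from shared neighborhood profiles."""

    gene_ids: list
    values: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ModulePartition:
    """Gene -> module label map; ``unassigned`` is the reserved non-label."""

    labels: pd.Series

    @property
    def module_names(self) -> list:
        sizes = self.sizes()
        return [m for m in sizes.index if m != UNASSIGNED]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])

    def modules(self) -> dict:
        return {m: self.genes_in(m) for m in self.module_names}

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("module").rename_axis("gene_id").reset_index()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def adjacency_matrix(x: ExpressionMatrix, power: int,
                     sign_mode: str = "unsigned",
                     on_zero_variance: str = "error") -> AdjacencyMatrix:
    """Soft-thresholded adjacency from gene-gene Pearson correlations.

    unsigned: a_ij = |cor|^power; signed: a_ij = ((1+cor)/2)^power.
    """
    if x.n_samples < 3:
        raise ValidationError("need >= 3 samples for correlations")
    if power < 1 or int(power) != power:
        raise ValidationError("power must be a natural number")
    vals = x.values
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        flat = [g for g, s in zip(x.gene_ids, sd) if s == 0]
        if on_zero_variance == "drop":
            logger.info("dropping %d zero-variance genes", len(flat))
            keep = sd > 0
            vals = vals[keep]
            gene_ids = [g for g, k in zip(x.gene_ids, keep) if k]
        else:
            raise ValidationError(f"zero-variance genes: {flat[:10]}")
    else:
        gene_ids = x.gene_ids
    cor = np.corrcoef(vals)
    cor = np.clip(cor, -1.0, 1.0)
    if sign_mode == "unsigned":
        a = np.abs(cor) ** power
    elif sign_mode == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValidationError(f"unknown sign_mode {sign_mode!r}")
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return AdjacencyMatrix(gene_ids, a, power=int(power), sign_mode=sign_mode)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple:
    """(r2, slope) of the log-log degree-distribution regression.

    Connectivities are split into equal-count bins on log10(k); the
    regressed "frequency" is the density estimate count / bin-width (a
    power-law degree distribution stays log-log linear under this
    change of variable), against the bin's mean log-connectivity.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 2 * n_bins:
        n_bins = max(2, len(k) // 2)
    logk = np.sort(np.log10(k))
    edges_idx = np.linspace(0, len(logk), n_bins + 1).astype(int)
    mean_logk, logdens = [], []
    for a, b in zip(edges_idx[:-1], edges_idx[1:]):
        chunk = logk[a:b]
        if len(chunk) == 0:
            continue
        width = chunk[-1] - chunk[0]
        if width <= 0:
            continue
        mean_logk.append(chunk.mean())
        logdens.append(np.log10(len(chunk) / (len(k) * width)))
    mean_logk, logdens = np.asarray(mean_logk), np.asarray(logdens)
    if len(mean_logk) < 3 or np.ptp(mean_logk) < 1e-12:
        return 0.0, 0.0
    res = linregress(mean_logk, logdens)
    if not np.isfinite(res.rvalue):
        return 0.0, 0.0
    return float(res.rvalue ** 2), float(res.slope)


def pick_soft_threshold(x: ExpressionMatrix,
                        candidates: Sequence[int] = tuple(range(1, 13)),
                        target_r2: float = 0.9,
                        sign_mode: str = "unsigned",
                        n_bins: int = 10):
    """Smallest candidate power whose network approaches scale-free
    topology (r2 >= target with negative slope).

    Returns ``(power, fits, target_met)``; when no candidate reaches the
    target, ``power`` is the candidate maximizing r2 and ``target_met``
    is False — the caller must not treat it as a silent success.
    """
    candidates = list(candidates)
    if not candidates or any(candidates[i] >= candidates[i + 1]
                             for i in range(len(candidates) - 1)):
        raise ValidationError("candidates must be non-empty and ascending")
    vals = x.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    vals = vals[keep]
    cor = np.clip(np.corrcoef(vals), -1.0, 1.0)
    if sign_mode == "unsigned":
        base = np.abs(cor)
    else:
        base = (1.0 + cor) / 2.0
    fits = []
    for p in candidates:
        a = base ** p
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        fits.append(ScaleFreeFit(power=int(p), r2=r2, slope=slope,
                                 mean_connectivity=float(k.mean())))
    for f in fits:
        if f.r2 >= target_r2 and f.slope < 0:
            return f.power, fits, True
    best = max(fits, key=lambda f: (f.r2 if f.slope < 0 else -1.0))
    logger.warning("pick_soft_threshold: target r2=%.2f not met; best power "
                   "%d (r2=%.3f)", target_r2, best.power, best.r2)
    return best.power, fits, False


def topological_overlap(a: AdjacencyMatrix) -> TOMatrix:
    """TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    A = a.values
    n = A.shape[0]
    k = a.connectivity
    shared = A @ A - 2.0 * A  # removes u=i and u=j terms (diag = 1)
    numer = shared + A
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(a.gene_ids, tom)


def cluster_dendrogram(d: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration of a symmetric dissimilarity matrix.

    Returns a scipy linkage matrix Z with non-decreasing merge heights.
    """
    d = np.asarray(d, dtype=float)
    if np.isnan(d).any():
        raise ValidationError("NaN dissimilarity")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0):
        raise ValidationError("dissimilarity must be symmetric with zero diagonal")
    return average(squareform(d, checks=False))


def _large_clusters(assignments: np.ndarray, min_size: int):
    uniq, counts = np.unique(assignments, return_counts=True)
    big = uniq[counts >= min_size]
    order = np.argsort(assignments, kind="stable")
    sorted_assign = assignments[order]
    out = []
    for c in big:
        left = np.searchsorted(sorted_assign, c, side="left")
        right = np.searchsorted(sorted_assign, c, side="right")
        out.append(order[left:right])
    return out


def cut_modules(Z: np.ndarray, d: np.ndarray, min_size: int = 20,
                deep_split: int = 2, max_height: float = 0.99,
                pam_stage: bool = True,
                gene_ids: Optional[Sequence] = None) -> ModulePartition:
    """Two-stage hybrid adaptive tree cut.

    Stage 1 scans static cuts of the dendrogram (capped at ``max_height``
    of the top merge) and keeps, at the cut yielding the most of them,
    branches that are both large enough (``min_size``) and internally
    coherent — normalized mean internal dissimilarity at most a ceiling
    that ``deep_split`` (0 = conservative .. 4 = aggressive) relaxes.
    Stage 2 (the PAM-like stage) assigns every leftover gene to the
    module of smallest average dissimilarity.  Modules are ordered by
    size and named with the conventional color sequence.
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    if not 0 <= deep_split <= 4:
        raise ValidationError("deep_split must be in 0..4")
    n = d.shape[0]
    if gene_ids is None:
        gene_ids = list(range(n))
    heights = Z[:, 2]
    top = heights.max() if len(heights) else 0.0

    offdiag = d[np.triu_indices(n, k=1)]
    lo = np.quantile(offdiag, 0.05) if len(offdiag) else 0.0
    hi = offdiag.max() if len(offdiag) else 1.0
    span = max(hi - lo, 1e-12)
    scatter_ceiling = _MAX_CORE_SCATTER[deep_split]

    all_idx = np.arange(n)

    def qualifying(assign: np.ndarray) -> list:
        # a branch counts as a module if, after stripping incoherent
        # members, at least min_size remain.  A member is stripped when
        # its mean dissimilarity to the branch exceeds the deep_split
        # ceiling (kills all-noise branches) or sits closer to the
        # branch's exterior level than to its core (strips noise genes
        # chained onto a real branch)
        good = []
        for members in _large_clusters(assign, min_size):
            sub = d[np.ix_(members, members)]
            m = len(members)
            avg_to_rest = sub.sum(axis=1) / (m - 1)
            keep = (avg_to_rest - lo) / span <= scatter_ceiling
            if m < n:
                outside = np.setdiff1d(all_idx, members, assume_unique=True)
                ext = d[np.ix_(members, outside)].mean()
                core = np.median(avg_to_rest)
                if ext > core:
                    keep &= avg_to_rest <= core + 0.5 * (ext - core)
            if keep.sum() >= min_size:
                good.append(members[keep])
        return good

    if top <= 0:  # fully degenerate tree: everything identical
        assign = np.ones(n, dtype=int)
        best_clusters = qualifying(assign)
        if not best_clusters:
            best_clusters = [np.arange(n)]
    else:
        cut_cap = max_height * top
        cand = np.unique(heights)
        cand = cand[cand <= cut_cap]
        if len(cand) > 60:  # scan quantile levels; the exact cut inside a
            cand = np.quantile(cand, np.linspace(0, 1, 60))  # gap is immaterial
        eps = 1e-10 * max(top, 1.0)
        cuts = np.append(cand + eps, cut_cap)
        # prefer more qualifying branches, then larger total membership so
        # each branch is taken as high (maximal) as coherence allows
        best_clusters, best_key, best_h = [], (-1, -1), None
        for h in cuts:
            assign = fcluster(Z, t=h, criterion="distance")
            good = qualifying(assign)
            key = (len(good), sum(len(g) for g in good))
            if key > best_key:
                best_clusters, best_key, best_h = good, key, h
        logger.debug("cut_modules: %d modules at height %.4f",
                     best_key[0], best_h)

    labels = np.full(n, -1, dtype=int)
    order = np.argsort([-len(m) for m in best_clusters], kind="stable")
    for rank, idx in enumerate(order):
        labels[best_clusters[idx]] = rank

    if pam_stage and (labels == -1).any() and len(best_clusters) > 0:
        module_index = {r: best_clusters[idx] for r, idx in enumerate(order)}
        for i in np.flatnonzero(labels == -1):
            avg = {r: d[i, members].mean() for r, members in module_index.items()}
            labels[i] = min(avg, key=avg.get)

    def name(lab: int) -> str:
        if lab < 0:
            return UNASSIGNED
        if lab < len(MODULE_COLORS):
            return MODULE_COLORS[lab]
        return f"module{lab + 1}"

    series = pd.Series([name(l) for l in labels], index=list(gene_ids),
                       name="module")
    return ModulePartition(series)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Detect co-expression modules among the columns (genes) of an
    expression array.

    Follows the FeatureAgglomeration convention: ``fit(X)`` with X of
    shape (n_samples, n_genes); ``labels_`` has one entry per gene
    (module index, -1 for unassigned) and ``module_colors_`` the
    conventional color names.

    Parameters
    ----------
    power : int or "auto"
        Soft-threshold power; "auto" picks the smallest power reaching
        ``target_r2`` scale-free fit over ``power_candidates``.
    sign_mode : {"unsigned", "signed"}
    min_module_size, deep_split, max_height, pam_stage
        Hybrid tree-cut parameters.
    """

    def __init__(self, power="auto", sign_mode="unsigned", min_module_size=20,
                 deep_split=2, max_height=0.99, pam_stage=True,
                 power_candidates=tuple(range(1, 13)), target_r2=0.9):
        self.power = power
        self.sign_mode = sign_mode
        self.min_module_size = min_module_size
        self.deep_split = deep_split
        self.max_height = max_height
        self.pam_stage = pam_stage
        self.power_candidates = power_candidates
        self.target_r2 = target_r2

    def fit(self, X, y=None):
        gene_ids = list(X.columns) if hasattr(X, "columns") else None
        X = check_array(X)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
        xm = ExpressionMatrix(pd.DataFrame(
            np.asarray(X).T, index=gene_ids,
            columns=[f"s{i}" for i in range(X.shape[0])]))
        self.partition_ = fit_modules(
            xm, power=self.power, sign_mode=self.sign_mode,
            min_module_size=self.min_module_size, deep_split=self.deep_split,
            max_height=self.max_height, pam_stage=self.pam_stage,
            power_candidates=self.power_candidates, target_r2=self.target_r2,
            _store=self)
        color_to_idx = {c: i for i, c in
                        enumerate(self.partition_.module_names)}
        self.labels_ = np.array([
            color_to_idx.get(lbl, -1) for lbl in self.partition_.labels
        ])
        self.module_colors_ = list(self.partition_.module_names)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fit_modules(x: ExpressionMatrix, power="auto", sign_mode="unsigned",
                min_module_size=20, deep_split=2, max_height=0.99,
                pam_stage=True, power_candidates=tuple(range(1, 13)),
                target_r2=0.9, _store=None) -> ModulePartition:
    """Run the full chain adjacency -> TOM -> dendrogram -> hybrid cut."""
    if power == "auto":
        chosen, fits, met = pick_soft_threshold(
            x, candidates=power_candidates, target_r2=target_r2,
            sign_mode=sign_mode)
    else:
        chosen, fits, met = int(power), [], True
    adj = adjacency_matrix(x, power=chosen, sign_mode=sign_mode,
                           on_zero_variance="drop")
    tom = topological_overlap(adj)
    d = tom.dissimilarity
    Z = cluster_dendrogram(d)
    part = cut_modules(Z, d, min_size=min_module_size, deep_split=deep_split,
                       max_height=max_height, pam_stage=pam_stage,
                       gene_ids=adj.gene_ids)
    dropped = [g for g in x.gene_ids if g not in set(adj.gene_ids)]
    if dropped:
        part = ModulePartition(pd.concat([
            part.labels,
            pd.Series(UNASSIGNED, index=dropped, name="module"),
        ]))
    if _store is not None:
        _store.power_ = chosen
        _store.scale_free_fits_ = fits
        _store.scale_free_target_met_ = met
        _store.linkage_ = Z
    return part
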