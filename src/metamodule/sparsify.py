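"""Module sparsification: how much of a module's predictive power rides
on its most individually predictive genes?

Genes are ranked once by their individual recurrence AUC (direction
folded, since members may anti-correlate with the meta-gene) and removed
from the module in that fixed order; after each removal the remaining
genes' PC1 meta-gene and its AUC are recomputed.  The removals made
while the AUC stays at or above a retention fraction (default 90%) of
the full-module AUC — capped at 100 — form the "sparse module": the
genes the module could least afford to lose, and the natural candidate
for a reduced assay panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import delong_test, roc_auc
from .io import ExpressionMatrix, PhenotypeTable, ValidationError
from .metagene import compute_metagenes

logger = logging.getLogger(__name__)


@dataclass
class SparsificationTrace:
    """Removal-by-removal record of the sparsification loop."""

    removed_genes: list             # in removal order
    auc_after_removal: list         # meta-gene AUC after each removal
    full_auc: float
    threshold: float
    cap: int
    sparse_set: list
    termination: str                # "threshold" | "cap" | "exhausted"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": range(1, len(self.removed_genes) + 1),
            "gene": self.removed_genes,
            "auc": self.auc_after_removal,
        })


def _module_auc(x: ExpressionMatrix, genes: Sequence,
                y: np.ndarray) -> float:
    if len(genes) >= 2:
        mg = compute_metagenes(x, {"m": list(genes)}).series("m")
        return roc_auc(mg.to_numpy(), y).auc
    expr = x.data.loc[genes[0]].to_numpy()
    auc = roc_auc(expr, y).auc
    return auc


def per_gene_auc(x: ExpressionMatrix, genes: Sequence,
                 pheno: PhenotypeTable, fold: bool = True) -> pd.DataFrame:
    """Individual recurrence AUC per module gene, with a paired DeLong
    test of each gene against the module meta-gene.

    With ``fold=True`` the ranking AUC is max(AUC, 1-AUC); the unfolded
    value is always reported alongside.  Sorted descending, ties broken
    lexicographically by gene id.
    """
    pheno = pheno.aligned_to(x)
    y = pheno.recurrence.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes required")
    present = [g for g in genes if g in x.data.index]
    skipped = len(genes) - len(present)
    if skipped:
        logger.info("per_gene_auc: %d genes absent from matrix, skipped",
                    skipped)
    mg = compute_metagenes(x, {"m": present}).series("m").to_numpy()
    rows = []
    for g in present:
        expr = x.data.loc[g].to_numpy()
        auc_raw = roc_auc(expr, y).auc
        auc_rank = max(auc_raw, 1 - auc_raw) if fold else auc_raw
        scores = expr if auc_raw >= 0.5 or not fold else -expr
        dl = delong_test(scores, mg, y)
        rows.append({"gene": g, "auc": auc_rank, "auc_unfolded": auc_raw,
                     "delong_p_vs_metagene": dl.p_value})
    out = pd.DataFrame(rows).sort_values(
        ["auc", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def sparsify_module(x: ExpressionMatrix, genes: Sequence,
                    pheno: PhenotypeTable, threshold: float = 0.90,
                    cap: int = 100, rerank: bool = False,
                    inclusive: bool = True) -> SparsificationTrace:
    """Greedy removal of the most individually predictive genes.

    Stops when the recomputed meta-gene AUC drops below
    ``threshold * full_auc``, when ``cap`` removals have been made, or
    when fewer than 2 genes would remain.  ``inclusive=True`` (default)
    counts the removal that crosses the threshold as part of the sparse
    set; ``rerank=True`` recomputes the per-gene ranking after every
    removal instead of using the static order.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    genes = [g for g in genes if g in x.data.index]
    if len(genes) < 3:
        raise ValidationError("module must have >= 3 genes")
    pheno = pheno.aligned_to(x)
    y = pheno.recurrence.to_numpy()
    full_auc = _module_auc(x, genes, y)
    if full_auc <= 0.5:
        raise ValidationError("module not predictive (AUC <= 0.5); "
                              "sparsification undefined")
    floor = threshold * full_auc

    ranking = per_gene_auc(x, genes, pheno)["gene"].tolist()
    remaining = list(genes)
    removed, aucs = [], []
    termination = "exhausted"
    while True:
        if len(removed) >= cap:
            termination = "cap"
            break
        if len(remaining) <= 2:
            termination = "exhausted"
            break
        if rerank:
            ranking = per_gene_auc(x, remaining, pheno)["gene"].tolist()
            top = ranking[0]
        else:
            top = next(g for g in ranking if g in set(remaining))
        remaining.remove(top)
        removed.append(top)
        auc = _module_auc(x, remaining, y)
        aucs.append(auc)
        if auc < floor:
            termination = "threshold"
            break

    if termination == "threshold":
        sparse = removed if inclusive else removed[:-1]
    else:
        sparse = removed
    return SparsificationTrace(
        removed_genes=removed, auc_after_removal=aucs, full_auc=full_auc,
        threshold=threshold, cap=cap, sparse_set=list(sparse),
        termination=termination)


def evaluate_sparse_cross_cohort(sparse_sets: Mapping[str, Sequence],
                                 cohorts: Mapping[str, tuple],
                                 full_module: Sequence) -> dict:
    """Evaluate every sparse set in every cohort against the full module.

    ``cohorts`` maps cohort name -> (ExpressionMatrix, PhenotypeTable).
    Returns per-(set, cohort) AUCs with DeLong comparisons to the full
    module's meta-gene in that cohort, plus pairwise overlap counts
    between the sparse sets.
    """
    if len(cohorts) < 2 or len(sparse_sets) < 1:
        raise ValidationError("need >= 2 cohorts and >= 1 sparse set")
    results = {"evaluations": [], "overlaps": {}}
    names = list(sparse_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            results["overlaps"][f"{a}|{b}"] = len(
                set(sparse_sets[a]) & set(sparse_sets[b]))
    for cname, (x, pheno) in cohorts.items():
        pheno = pheno.aligned_to(x)
        y = pheno.recurrence.to_numpy()
        full_present = [g for g in full_module if g in x.data.index]
        full_mg = compute_metagenes(x, {"m": full_present}).series("m")
        full = roc_auc(full_mg.to_numpy(), y)
        for sname, genes in sparse_sets.items():
            present = [g for g in genes if g in x.data.index]
            flagged = len(present) < 2
            if flagged:
                logger.warning("sparse set %s has %d gene(s) in cohort %s; "
                               "single-gene score used", sname, len(present),
                               cname)
                scores = x.data.loc[present[0]].to_numpy()
            else:
                scores = compute_metagenes(
                    x, {"m": present}).series("m").to_numpy()
            sp = roc_auc(scores, y)
            dl = delong_test(scores, full_mg.to_numpy(), y)
            results["evaluations"].append({
                "sparse_set": sname, "cohort": cname,
                "sparse_auc": sp.auc, "sparse_se": sp.se,
                "full_auc": full.auc, "full_se": full.se,
                "delong_p": dl.p_value, "single_gene_fallback": flagged,
            })
    return results
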