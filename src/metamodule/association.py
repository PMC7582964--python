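"""Phenotype-association screens for modules and genes.

Covers the recurrence t-test (module selection), WHO-grade ANOVA,
time-to-recurrence correlation, the transcription-factor marker screen
(enrichment hit AND consistent differential expression in every
validation cohort), and the intra-chromosomal distance / co-expression
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (ExpressionMatrix, GeneAnnotation, PhenotypeTable,
                 ValidationError)
from .metagene import MetageneMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """One statistical screen's outcome for a module or gene."""

    unit: str
    test: str                       # "t-test" | "anova" | "pearson"
    statistic: float
    p_value: float
    group_means: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    direction: Optional[str] = None  # "up" / "down" in recurrent, or sign

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _aligned_scores(values, pheno: PhenotypeTable) -> pd.Series:
    s = pd.Series(values) if not isinstance(values, pd.Series) else values
    missing = [i for i in s.index if i not in pheno.data.index]
    if missing:
        raise ValidationError(f"samples absent from phenotype: {missing[:5]}")
    return s


def recurrence_ttest(values, pheno: PhenotypeTable, unit: str = "module",
                     equal_var: bool = False) -> AssociationResult:
    """Two-sided Welch t-test of per-sample scores between recurrent and
    non-recurrent tumors (Student's pooled test with ``equal_var=True``)."""
    s = _aligned_scores(values, pheno)
    rec = pheno.recurrence.loc[s.index]
    g1 = s[rec == 1].to_numpy(dtype=float)
    g0 = s[rec == 0].to_numpy(dtype=float)
    if len(g1) < 2 or len(g0) < 2:
        raise ValidationError("both outcome groups need >= 2 samples")
    if g1.std(ddof=1) == 0 and g0.std(ddof=1) == 0:
        if g1.mean() == g0.mean():
            logger.info("recurrence_ttest: degenerate equal groups, p = 1")
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(g1.mean() - g0.mean()), 0.0
    else:
        t, p = stats.ttest_ind(g1, g0, equal_var=equal_var)
    direction = "up" if g1.mean() > g0.mean() else "down"
    return AssociationResult(
        unit=unit, test="t-test", statistic=float(t), p_value=float(p),
        group_means={"recurrent": float(g1.mean()),
                     "non_recurrent": float(g0.mean())},
        group_sizes={"recurrent": len(g1), "non_recurrent": len(g0)},
        direction=direction,
    )


def grade_anova(values, pheno: PhenotypeTable,
                unit: str = "module") -> AssociationResult:
    """One-way fixed-effects ANOVA of scores across WHO grades."""
    s = _aligned_scores(values, pheno)
    grade = pheno.who_grade.loc[s.index]
    groups = {int(g): s[grade == g].to_numpy(dtype=float)
              for g in sorted(grade.dropna().unique())}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValidationError("need >= 2 WHO grades with >= 2 samples each")
    arrays = list(groups.values())
    if all(a.std(ddof=1) == 0 for a in arrays) and \
            len({a.mean() for a in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays)
        if np.isnan(f):  # identical groups with zero within-variance
            f, p = 0.0, 1.0
    return AssociationResult(
        unit=unit, test="anova", statistic=float(f), p_value=float(p),
        group_means={f"grade{g}": float(v.mean()) for g, v in groups.items()},
        group_sizes={f"grade{g}": len(v) for g, v in groups.items()},
    )


def ttr_correlation(values, pheno: PhenotypeTable, mode: str = "year-binned",
                    min_bin_n: int = 3, unit: str = "module") -> AssociationResult:
    """Pearson correlation of scores with time-to-recurrence (years),
    over recurrent samples.

    mode="per-sample" correlates raw per-sample values; mode="year-binned"
    (default) averages scores within integer years of time-to-recurrence
    (bins with >= ``min_bin_n`` samples) and correlates the bin means.
    """
    s = _aligned_scores(values, pheno)
    ttr = pheno.data["time_to_recurrence"].loc[s.index]
    mask = ttr.notna()
    x, t = s[mask].to_numpy(dtype=float), ttr[mask].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValidationError("need >= 3 recurrent samples with TTR")
    if mode == "per-sample":
        xs, ts = x, t
    elif mode == "year-binned":
        years = np.floor(t).astype(int)
        xs, ts = [], []
        for y in np.unique(years):
            sel = years == y
            if sel.sum() >= min_bin_n:
                xs.append(x[sel].mean())
                ts.append(float(y))
        xs, ts = np.asarray(xs), np.asarray(ts)
        if len(xs) < 3:
            raise ValidationError("fewer than 3 usable year bins")
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if np.std(xs) == 0 or np.std(ts) == 0:
        raise ValidationError("constant values; correlation undefined")
    r, p = stats.pearsonr(ts, xs)
    return AssociationResult(
        unit=unit, test="pearson", statistic=float(r), p_value=float(p),
        group_sizes={"n_points": len(xs)},
        direction="positive" if r >= 0 else "negative",
    )


def tf_marker_screen(enrichment: pd.DataFrame,
                     cohorts: Sequence[tuple],
                     q_alpha: float = 0.05,
                     p_alpha: float = 0.05,
                     equal_var: bool = False) -> pd.DataFrame:
    """Transcription-factor markers: enrichment q < ``q_alpha`` AND
    differential expression between recurrent and non-recurrent tumors
    (t-test p < ``p_alpha``) in EVERY cohort, with consistent direction.

    ``enrichment`` needs columns ``term`` and ``q``; the term name is
    taken as the TF gene symbol.  ``cohorts`` is a list of
    (ExpressionMatrix, PhenotypeTable) validation pairs.  Returns a frame
    with the retained TFs, their direction in recurrent tumors, and
    per-cohort t-test and grade-ANOVA p-values.
    """
    if len(cohorts) == 0:
        raise ValidationError("empty cohort list")
    hits = enrichment.loc[enrichment["q"] < q_alpha, "term"]
    rows = []
    for tf in hits:
        symbol = str(tf).upper()
        record = {"tf": symbol, "q": float(
            enrichment.loc[enrichment["term"] == tf, "q"].iloc[0])}
        directions, keep = [], True
        for i, (x, pheno) in enumerate(cohorts, start=1):
            match = [g for g in x.gene_ids if str(g).upper() == symbol]
            if not match:
                logger.info("TF %s not measured in cohort %d; excluded",
                            symbol, i)
                keep = False
                break
            expr = x.data.loc[match[0]]
            tt = recurrence_ttest(expr, pheno, unit=symbol,
                                  equal_var=equal_var)
            av = grade_anova(expr, pheno, unit=symbol)
            record[f"ttest_p_cohort{i}"] = tt.p_value
            record[f"anova_p_cohort{i}"] = av.p_value
            directions.append(tt.direction)
            if tt.p_value >= p_alpha:
                keep = False
                break
        if keep and len(set(directions)) == 1:
            record["direction"] = directions[0]
            rows.append(record)
    return pd.DataFrame(rows)


def linkage_distance_correlation(x: ExpressionMatrix, genes: Sequence,
                                 ann: GeneAnnotation,
                                 n_permutations: int = 1000,
                                 seed: int = 0) -> AssociationResult:
    """Correlation between intra-chromosomal genomic separation and
    co-expression over all same-chromosome gene pairs in ``genes``.

    The p-value comes from permuting gene positions within the subset
    (seeded), which preserves the correlation structure of expression.
    """
    genes = [g for g in genes if g in x.data.index and g in ann.data.index]
    if len(genes) < 2:
        raise ValidationError("need >= 2 annotated, measured genes")
    chrom = ann.data.loc[genes, "chromosome"].to_numpy()
    pos = ann.data.loc[genes, "start"].to_numpy(dtype=float)
    cor = np.corrcoef(x.data.loc[genes].to_numpy())
    iu = np.triu_indices(len(genes), k=1)
    same = chrom[iu[0]] == chrom[iu[1]]
    if not same.any():
        raise ValidationError("no intra-chromosomal pair")

    def pair_stat(p):
        sep = np.abs(p[iu[0]] - p[iu[1]])[same]
        co = cor[iu][same]
        if np.std(sep) == 0 or np.std(co) == 0:
            return 0.0
        return float(np.corrcoef(sep, co)[0, 1])

    observed = pair_stat(pos)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pos)
        if abs(pair_stat(perm)) >= abs(observed):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    n_pairs = int(same.sum())
    return AssociationResult(
        unit="linkage", test="pearson", statistic=observed, p_value=float(p),
        group_sizes={"n_pairs": n_pairs},
        direction="positive" if observed >= 0 else "negative",
    )
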