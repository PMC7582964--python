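"""Gene-set over-representation analysis over GMT libraries.

A module's gene list is tested against each library term with the
hypergeometric upper tail (Fisher's one-sided exact test), with
Benjamini-Hochberg q-values across the library.  The universe defaults
to the genes actually measured on the platform — material when the
platform is a targeted cancer panel rather than genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetLibrary, ValidationError


@dataclass
class EnrichmentResult:
    """One term's over-representation outcome."""

    term: str
    overlap: int          # k
    module_size: int      # m (within universe)
    term_size: int        # K (within universe)
    universe_size: int    # N
    p: float
    q: float
    overlap_genes: tuple


def overrepresentation_test(module_genes: Sequence, library: GeneSetLibrary,
                            universe: Sequence) -> pd.DataFrame:
    """Hypergeometric P(X >= k) per term, BH-adjusted across the library.

    Gene identifiers match case-insensitively.  Returns a frame sorted by
    q then p then term, with columns term/overlap/module_size/term_size/
    universe_size/p/q/overlap_genes.
    """
    uni = {str(g).upper() for g in universe}
    mod = {str(g).upper() for g in module_genes} & uni
    if not mod:
        raise ValidationError("module has no genes in the universe")
    N, m = len(uni), len(mod)
    rows = []
    for term in library.terms:
        members = {str(g).upper() for g in library[term]} & uni
        if not members:
            continue
        K = len(members)
        overlap = mod & members
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, m))
        rows.append({"term": term, "overlap": k, "module_size": m,
                     "term_size": K, "universe_size": N, "p": min(p, 1.0),
                     "overlap_genes": tuple(sorted(overlap))})
    if not rows:
        raise ValidationError("no library terms intersect the universe")
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["q", "p", "term"], kind="mergesort")
    return df.reset_index(drop=True)


def rank_terms(results: pd.DataFrame, top_n: int,
               by: str = "q") -> pd.DataFrame:
    """Top terms by ascending q (ties by p, then term name).

    ``by="neglog10q"`` ranks by descending -log10(q) — the same order,
    offered for plotting conventions.
    """
    if top_n <= 0:
        raise ValidationError("top_n must be positive")
    if len(results) == 0:
        raise ValidationError("empty results")
    if by not in ("q", "neglog10q"):
        raise ValidationError(f"unknown ranking key {by!r}")
    out = results.sort_values(["q", "p", "term"], kind="mergesort")
    return out.head(top_n).reset_index(drop=True)
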