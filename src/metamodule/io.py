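"""Input/output and validated in-memory containers.

Expression data travel as :class:`ExpressionMatrix` (genes x samples,
log2-scale after preprocessing), phenotypes as :class:`PhenotypeTable`,
gene sets as :class:`GeneSetLibrary`, and genomic coordinates as a
:class:`GeneAnnotation` table.  All containers wrap pandas objects and
validate their invariants on construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = (
    "sample_id",
    "recurrence",
    "who_grade",
    "simpson_grade",
    "time_to_recurrence",
    "follow_up",
    "batch",
)


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with unique, ordered identifiers.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.  Values are
        real-valued expression (log2 scale once preprocessing has run).
    stages : tuple of str
        Provenance of preprocessing stages already applied, in order.
    """

    data: pd.DataFrame
    stages: tuple = ()

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        if self.data.isna().any().any():
            bad = np.argwhere(self.data.isna().to_numpy())
            g, s = bad[0]
            raise ValidationError(
                f"missing value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r} ({len(bad)} total)"
            )
        self.data = self.data.astype(float)
        self.stages = tuple(self.stages)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], stages=self.stages)

    def subset_samples(self, samples: Iterable) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)], stages=self.stages)

    def with_stage(self, name: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data, stages=self.stages + (name,))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=0, atol=0)
        )


@dataclass
class PhenotypeTable:
    """Per-sample clinical annotations keyed by sample id.

    ``recurrence`` is binary (1 = recurred or progressed), ``who_grade``
    ordinal in {1,2,3}, ``simpson_grade`` ordinal in {1..5} or missing,
    ``time_to_recurrence`` / ``follow_up`` in years, ``batch`` a cohort
    label.  Missing modeled covariates are flagged, never silently
    dropped: downstream stages decide exclusion.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in phenotype table")
        for col in ("recurrence", "who_grade", "simpson_grade",
                    "time_to_recurrence", "follow_up"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if "batch" not in df.columns:
            df["batch"] = "cohort0"
        rec = df["recurrence"]
        bad = df.index[~rec.isin([0, 1])]
        if len(bad):
            raise ValidationError(f"recurrence outside {{0,1}} for samples {list(bad)[:5]}")
        who = df["who_grade"].dropna()
        bad = who.index[~who.isin([1, 2, 3])]
        if len(bad):
            raise ValidationError(f"who_grade outside {{1,2,3}} for samples {list(bad)[:5]}")
        sg = df["simpson_grade"].dropna()
        bad = sg.index[~sg.isin([1, 2, 3, 4, 5])]
        if len(bad):
            raise ValidationError(f"simpson_grade outside 1..5 for samples {list(bad)[:5]}")
        ttr = df["time_to_recurrence"]
        bad = df.index[ttr.notna() & (df["recurrence"] == 0)]
        if len(bad):
            raise ValidationError(
                f"time_to_recurrence present for non-recurrent samples {list(bad)[:5]}"
            )
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def recurrence(self) -> pd.Series:
        return self.data["recurrence"].astype(int)

    @property
    def who_grade(self) -> pd.Series:
        return self.data["who_grade"]

    def missing_flags(self) -> pd.DataFrame:
        """Boolean mask of missing modeled covariates per sample."""
        return self.data[["who_grade", "simpson_grade"]].isna()

    def subset(self, samples: Iterable) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(samples)])

    def aligned_to(self, x: ExpressionMatrix) -> "PhenotypeTable":
        missing = [s for s in x.sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from phenotype table: {missing[:5]}")
        return self.subset(x.sample_ids)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path)


@dataclass
class GeneSetLibrary:
    """Named gene sets (e.g. GO terms or transcription-factor target lists)."""

    sets: dict  # term -> list of gene symbols (upper-cased)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"term {term!r} has no member genes")

    @property
    def terms(self) -> list:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term):
        return self.sets[term]


@dataclass
class GeneAnnotation:
    """Genomic coordinates per gene: chromosome and start position (bp)."""

    data: pd.DataFrame  # index gene_id; columns chromosome, start

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        if "gene_id" in df.columns:
            df = df.set_index("gene_id")
        if df.index.has_duplicates:
            raise ValidationError("duplicate gene ids in annotation")
        if (df["start"] < 0).any():
            raise ValidationError("negative start positions")
        self.data = df[["chromosome", "start"]]


@dataclass
class AnalysisConfig:
    """Run configuration with the pipeline's default thresholds."""

    module_ttest_alpha: float = 0.05
    enrichment_q_alpha: float = 0.05
    scale_free_r2_target: float = 0.9
    sparsify_retention: float = 0.90
    sparsify_cap: int = 100
    cv_folds: int = 10
    power_candidates: tuple = tuple(range(1, 13))
    min_module_size: int = 20
    deep_split: int = 2
    max_height: float = 0.99
    pam_stage: bool = True
    sign_mode: str = "unsigned"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("module_ttest_alpha", "enrichment_q_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValidationError(f"{name} must lie in (0,1), got {a}")
        if not 0 < self.sparsify_retention <= 1:
            raise ValidationError("sparsify_retention must lie in (0,1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.sparsify_cap < 1:
            raise ValidationError("sparsify_cap must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "power_candidates" in raw:
            raw["power_candidates"] = tuple(raw["power_candidates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["power_candidates"] = list(d["power_candidates"])
        return d


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _detect_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_matrix(path, orientation: str = "rows-are-genes",
                           collapse: str = "max-variance") -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    orientation : {"rows-are-genes", "rows-are-samples"}
        Which axis the file's rows represent.  A transposed file read with
        the opposite flag yields an identical object.
    collapse : {"max-variance", "mean", "error"}
        Rule for multiple rows sharing one gene id (multi-probe genes):
        keep the row of maximal variance (default), average rows, or
        reject the file.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"empty file: {path}")
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        kind = "sample" if orientation == "rows-are-genes" else "gene"
        raise ValidationError(f"duplicate {kind} ids in header: {dups[:10]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"no data rows/columns in {path}")
    if orientation == "rows-are-samples":
        df = df.T
    elif orientation != "rows-are-genes":
        raise ValidationError(f"unknown orientation {orientation!r}")
    # locate non-numeric / blank cells before coercion so we can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    blank = df.isna()
    offending = bad | blank
    if offending.any().any():
        g, s = np.argwhere(offending.to_numpy())[0]
        kind = "blank" if blank.iloc[g, s] else f"non-numeric ({df.iloc[g, s]!r})"
        raise ValidationError(
            f"{kind} cell at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    df = numeric
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:10]}")
    if df.index.has_duplicates:
        if collapse == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        n_dup = int(df.index.duplicated().sum())
        if collapse == "mean":
            df = df.groupby(level=0, sort=False).mean()
        elif collapse == "max-variance":
            order = {g: i for i, g in enumerate(dict.fromkeys(df.index))}
            variances = df.var(axis=1, ddof=1).to_numpy()
            keep = (
                pd.DataFrame({"gene": df.index, "var": variances, "pos": range(len(df))})
                .sort_values("var", ascending=False, kind="mergesort")
                .drop_duplicates("gene")
                .sort_values("pos")["pos"]
                .to_numpy()
            )
            df = df.iloc[sorted(keep)]
            df = df.loc[sorted(df.index, key=order.__getitem__)]
        else:
            raise ValidationError(f"unknown collapse rule {collapse!r}")
        logger.info("collapsed %d duplicate gene rows by %s", n_dup, collapse)
    return ExpressionMatrix(df)


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a phenotype CSV (columns per :data:`PHENOTYPE_COLUMNS`)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError("phenotype CSV must have a sample_id column")
    n_missing = int(df["who_grade"].isna().sum()) if "who_grade" in df.columns else 0
    if n_missing:
        logger.info("%d samples flagged with missing who_grade", n_missing)
    return PhenotypeTable(df)


def read_gmt(path) -> GeneSetLibrary:
    """Read a GMT gene-set library (term TAB description TAB genes...)."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"line {lineno}: fewer than 3 tab-separated fields")
            term, desc = fields[0], fields[1]
            genes = [g.strip().upper() for g in fields[2:] if g.strip()]
            if not genes:
                raise ValidationError(f"line {lineno}: term {term!r} has no genes")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                logger.info("term %s: %d duplicate genes removed",
                            term, len(genes) - len(uniq))
            sets[term] = uniq
            descriptions[term] = desc
    if not sets:
        raise ValidationError(f"no terms in {path}")
    return GeneSetLibrary(sets, descriptions)


def read_gene_annotation(path) -> GeneAnnotation:
    """Read BED-like coordinates: chrom, start, end, gene_id (TSV, no header)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "gene_id"])
    return GeneAnnotation(df[["gene_id", "chromosome", "start"]])


def write_json_report(obj: Mapping, path) -> None:
    """Serialize a stage report to JSON (numpy scalars coerced)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
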