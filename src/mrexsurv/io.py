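"""Reading, validation and alignment of omics matrices, survival tables and annotations.

Matrices are plain TSV with ids in the first row/column; annotations are BED6
(0-based half-open, converted to 1-based closed coordinates on read); survival
tables are TSV with mandatory ``time`` and ``event`` columns, every remaining
numeric column being treated as a covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mrexsurv")

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "FeatureAnnotation",
    "GeneBlock",
    "read_omics_table",
    "write_omics_table",
    "read_survival_table",
    "read_bed6",
    "align_samples",
    "assemble_gene_block",
]


def _check_unique(ids, axis_name: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate {axis_name} ids: {sorted(map(str, dups))}")


@dataclass
class OmicsMatrix:
    """A samples x features real matrix (methylation or expression).

    ``values`` is an ``(n, q)`` float array; missing entries are NaN.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def q(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not present: {missing}")
        return OmicsMatrix(list(sample_ids), list(self.feature_ids), self.values[idx])

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        idx = pd.Index(self.feature_ids).get_indexer(list(feature_ids))
        if (idx < 0).any():
            missing = [f for f, i in zip(feature_ids, idx) if i < 0]
            raise KeyError(f"features not present: {missing}")
        return OmicsMatrix(list(self.sample_ids), list(feature_ids), self.values[:, idx])


@dataclass
class SurvivalTable:
    """Right-censored follow-up with covariates.

    ``time`` is observed follow-up (months, > 0); ``event`` is 1 for death and
    0 for censoring; ``covariates`` is an ``(n, m)`` frame (age, stage, ...).
    Constant covariate columns are dropped at construction; the remaining
    covariate matrix must have full column rank.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must equal the number of samples")
        if np.isnan(self.time).any():
            raise ValueError("missing follow-up times are not allowed")
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be positive")
        ev = np.unique(self.event[~pd.isna(self.event)])
        if pd.isna(self.event).any() or not np.isin(ev, [0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death), no missing")
        self.event = self.event.astype(int)
        if len(self.covariates):
            if len(self.covariates) != n:
                raise ValueError("covariate rows must match samples")
            self.covariates = self.covariates.set_axis(self.sample_ids, axis=0)
            keep = [c for c in self.covariates.columns if self.covariates[c].nunique() > 1]
            dropped = [c for c in self.covariates.columns if c not in keep]
            if dropped:
                logger.info("dropping constant covariate columns: %s", dropped)
            self.covariates = self.covariates[keep].astype(float)
            if keep:
                X = self.covariates.to_numpy()
                if np.linalg.matrix_rank(X - X.mean(0)) < X.shape[1]:
                    raise ValueError("covariate matrix is rank deficient")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def covariate_matrix(self) -> np.ndarray:
        if not len(self.covariates.columns):
            return np.empty((self.n, 0))
        return self.covariates.to_numpy(dtype=float)

    def subset(self, sample_ids) -> "SurvivalTable":
        idx = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (idx < 0).any():
            raise KeyError("samples not present in survival table")
        cov = self.covariates.iloc[idx] if len(self.covariates.columns) else pd.DataFrame()
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx], cov.reset_index(drop=True))


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic location of a gene or CpG site, 1-based closed coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.kind == "gene" and not self.start < self.end:
            raise ValueError(f"gene {self.feature_id}: start must be < end")
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start > end")


@dataclass
class GeneBlock:
    """One gene's aligned expression vector and CpG matrix."""

    gene_id: str
    G: np.ndarray
    M: np.ndarray
    cpg_ids: list[str]

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.G.shape[0]:
            raise ValueError("M must be n x p with n matching G")
        if self.M.shape[1] != len(self.cpg_ids):
            raise ValueError("cpg_ids must match M columns")
        if self.M.shape[1] < 1:
            raise ValueError("a gene block needs at least one CpG")
        if np.isnan(self.G).any() or np.isnan(self.M).any():
            raise ValueError("gene blocks must be complete (impute first)")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]


def read_omics_table(path, orientation: str = "samples") -> OmicsMatrix:
    """Read a TSV matrix; ``orientation`` says whether rows are ``samples`` or ``features``.

    Non-numeric cells become missing (NaN); the returned matrix is always
    samples x features.
    """
    if orientation not in ("samples", "features"):
        raise ValueError("orientation must be 'samples' or 'features'")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty omics table")
    _check_unique(df.index, "row")
    _check_unique(df.columns, "column")
    values = df.apply(pd.to_numeric, errors="coerce")
    if orientation == "features":
        values = values.T
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: %d missing entries after parsing", path, n_missing)
    return OmicsMatrix(list(values.index), list(values.columns), values.to_numpy(dtype=float))


def write_omics_table(matrix: OmicsMatrix, path, orientation: str = "samples") -> None:
    df = matrix.to_frame()
    if orientation == "features":
        df = df.T
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_survival_table(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table lacks mandatory column '{col}'")
    covar_cols = [c for c in df.columns if c not in ("time", "event")]
    return SurvivalTable(
        list(df.index.astype(str)),
        df["time"].to_numpy(),
        df["event"].to_numpy(),
        df[covar_cols].reset_index(drop=True),
    )


def write_survival_table(surv: SurvivalTable, path) -> None:
    df = pd.DataFrame({"time": surv.time, "event": surv.event}, index=surv.sample_ids)
    for c in surv.covariates.columns:
        df[c] = surv.covariates[c].to_numpy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_bed6(path, kind: str) -> list[FeatureAnnotation]:
    """Read BED6 (chrom, start, end, name, score, strand); 0-based half-open
    intervals are converted to the 1-based closed convention used internally."""
    feats: list[FeatureAnnotation] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    for row in df.itertuples(index=False):
        feats.append(
            FeatureAnnotation(
                feature_id=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start) + 1,
                end=int(row.end),
                strand=str(row.strand),
                kind=kind,
            )
        )
    _check_unique([f.feature_id for f in feats], kind)
    return feats


def write_bed6(feats, path) -> None:
    with open(path, "w") as fh:
        for f in feats:
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")


def align_samples(
    methyl: OmicsMatrix, expr: OmicsMatrix, surv: SurvivalTable
) -> tuple[OmicsMatrix, OmicsMatrix, SurvivalTable]:
    """Restrict all three inputs to their common samples, identically ordered.

    The order of the methylation matrix is kept; samples missing from any
    source are dropped (never imputed) and the per-source drop counts logged.
    """
    common = set(methyl.sample_ids) & set(expr.sample_ids) & set(surv.sample_ids)
    if not common:
        raise ValueError("no samples shared between methylation, expression and survival")
    order = [s for s in methyl.sample_ids if s in common]
    for name, ids in (
        ("methylation", methyl.sample_ids),
        ("expression", expr.sample_ids),
        ("survival", surv.sample_ids),
    ):
        dropped = len(ids) - len(order)
        if dropped:
            logger.info("align_samples: dropped %d samples from %s", dropped, name)
    return methyl.subset_samples(order), expr.subset_samples(order), surv.subset(order)


def promoter_window(gene: FeatureAnnotation, promoter_ext: int) -> tuple[int, int]:
    """1-based closed interval covering the gene body plus ``promoter_ext`` bp
    upstream of the transcription start site (strand-aware)."""
    if promoter_ext < 0:
        raise ValueError("promoter_ext must be >= 0")
    if gene.strand == "+":
        return gene.start - promoter_ext, gene.end
    return gene.start, gene.end + promoter_ext


def assemble_gene_block(
    gene: FeatureAnnotation,
    cpgs: list[FeatureAnnotation],
    methyl: OmicsMatrix,
    expr: OmicsMatrix,
    promoter_ext: int = 2000,
) -> GeneBlock | None:
    """Collect the CpGs falling in the gene body + promoter window into a block.

    Returns None (and logs) when no CpG lies in the window; the gene is then
    skipped rather than failing the run. CpGs inside two overlapping genes are
    assigned to both blocks.
    """
    lo, hi = promoter_window(gene, promoter_ext)
    hits = [
        c.feature_id
        for c in cpgs
        if c.chrom == gene.chrom and lo <= c.start <= hi
    ]
    hits = [c for c in hits if c in set(methyl.feature_ids)]
    if not hits:
        logger.info("gene %s: no CpGs in window [%d, %d], skipped", gene.feature_id, lo, hi)
        return None
    # keep genomic input order stable regardless of cpgs ordering
    hits = sorted(set(hits), key=methyl.feature_ids.index)
    if gene.feature_id not in expr.feature_ids:
        logger.info("gene %s: no expression column, skipped", gene.feature_id)
        return None
    g = expr.subset_features([gene.feature_id]).values[:, 0]
    m = methyl.subset_features(hits).values
    return GeneBlock(gene.feature_id, g, m, hits)
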