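"""End-to-end per-gene two-stage analysis.

read -> align -> impute -> transform (inverse-normal expression, standardized
methylation) -> per-gene blocks -> PVE screen -> for each retained gene and
each configured prediction model: weights -> MReX -> Cox mixed fit -> Wald
p-value -> ACAT combination -> per-model and combined BH FDR. Per-gene tasks
are independent; results are sorted by gene id so output is order-invariant.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .combine import acat_combine, bh_fdr, call_significant
from .coxmixed import CoxMixedConfig, fit_cox_mixed, wald_test
from .io import GeneBlock, SurvivalTable
from .prediction import PredictionFit, cross_validated_r2, fit_weights, impute_mrex
from .qc import (
    QcConfig,
    estimate_pve,
    impute_median,
    inverse_normal_transform,
    qc_filter_genes,
    standardize_features,
)

logger = logging.getLogger("mrexsurv")

RESULTS_SCHEMA = "mrexsurv-results-v1"

__all__ = ["PipelineConfig", "analyze_gene", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    methylation: str = ""
    expression: str = ""
    survival: str = ""
    genes_bed: str = ""
    cpgs_bed: str = ""
    methyl_orientation: str = "samples"
    expr_orientation: str = "samples"
    qc: QcConfig = field(default_factory=QcConfig)
    models: tuple = ("lmm", "lasso", "enet")
    enet_alpha: float = 0.5
    cv_folds: int = 5
    ties: str = "efron"
    fdr_threshold: float = 0.05
    promoter_ext: int = 2000
    seed: int = 0
    outdir: str = "results"
    n_jobs: int = 1
    with_cv_r2: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be nonempty")
        self.models = tuple(self.models)


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; the ``qc`` key nests QcConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    qc = QcConfig(**raw.pop("qc", {}))
    return PipelineConfig(qc=qc, **raw)


def _model_hyperparams(model: str, config: PipelineConfig) -> dict | None:
    if model == "enet":
        return {"alpha": config.enet_alpha}
    return None


def standardized_covariates(surv: SurvivalTable) -> np.ndarray:
    """Covariate matrix centered and scaled for a numerically stable Cox fit."""
    X = surv.covariate_matrix()
    if X.shape[1] == 0:
        return X
    sd = X.std(axis=0, ddof=1)
    return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def analyze_gene(
    block: GeneBlock,
    surv: SurvivalTable,
    config: PipelineConfig,
    injected_fits: dict[str, PredictionFit] | None = None,
) -> dict | None:
    """Two-stage analysis of one gene under every configured model.

    A model that fails on this gene gets a missing p-value and ACAT runs over
    the surviving models with renormalized (equal) weights; the gene is
    skipped only when every model fails. ``injected_fits`` supplies
    externally estimated weight vectors keyed by model tag.
    """
    X = standardized_covariates(surv)
    cox_cfg = CoxMixedConfig(ties=config.ties)
    rec: dict = {"gene_id": block.gene_id, "n": block.n, "n_cpgs": block.p}
    p_values, weights = [], []
    for model in config.models:
        cols = {f"b_{model}": np.nan, f"se_{model}": np.nan, f"z_{model}": np.nan,
                f"p_{model}": np.nan, f"sigma_c2_{model}": np.nan,
                f"converged_{model}": False}
        if config.with_cv_r2:
            cols[f"cv_r2_{model}"] = np.nan
        try:
            if injected_fits and model in injected_fits:
                fit = injected_fits[model]
            else:
                fit = fit_weights(block, model, _model_hyperparams(model, config),
                                  folds=config.cv_folds, seed=config.seed)
            mrex = impute_mrex(block, fit)
            cfit = fit_cox_mixed(surv, X, mrex, block.M, config=cox_cfg)
            wald = wald_test(cfit)
            cols.update({
                f"b_{model}": wald.effect, f"se_{model}": wald.se,
                f"z_{model}": wald.z, f"p_{model}": wald.p_value,
                f"sigma_c2_{model}": cfit.sigma_c2,
                f"converged_{model}": bool(cfit.converged),
            })
            if config.with_cv_r2:
                cols[f"cv_r2_{model}"] = cross_validated_r2(
                    block, model, folds=config.cv_folds, seed=config.seed,
                    hyperparams=_model_hyperparams(model, config))
            p_values.append(wald.p_value)
            weights.append(1.0)
        except Exception as exc:  # noqa: BLE001 - per-model failure is recoverable
            logger.warning("gene %s model %s failed: %s", block.gene_id, model, exc)
        rec.update(cols)
    if not p_values:
        logger.warning("gene %s: all models failed, skipped", block.gene_id)
        return None
    rec["n_models"] = len(p_values)
    rec["p_acat"] = acat_combine(p_values, weights).p_combined
    return rec


def prepare_inputs(config: PipelineConfig):
    """Read, align and transform the raw inputs; build and screen gene blocks.

    Returns (blocks, pve_report, survival) where blocks have already passed
    the CpG-count and PVE filters.
    """
    methyl = mio.read_omics_table(config.methylation, config.methyl_orientation)
    expr = mio.read_omics_table(config.expression, config.expr_orientation)
    surv = mio.read_survival_table(config.survival)
    genes = mio.read_bed6(config.genes_bed, kind="gene")
    cpgs = mio.read_bed6(config.cpgs_bed, kind="cpg")
    n_read = len(genes)
    methyl, expr, surv = mio.align_samples(methyl, expr, surv)

    methyl = impute_median(methyl, config.qc.max_missing_frac)
    expr = impute_median(expr, config.qc.max_missing_frac)
    expr_t = np.column_stack([
        inverse_normal_transform(expr.values[:, j], config.qc.inverse_normal_offset)
        for j in range(expr.q)
    ])
    expr = mio.OmicsMatrix(expr.sample_ids, expr.feature_ids, expr_t)
    methyl = standardize_features(methyl)

    blocks = []
    for gene in genes:
        blk = mio.assemble_gene_block(gene, cpgs, methyl, expr, config.promoter_ext)
        if blk is not None:
            blocks.append(blk)
    pves = {b.gene_id: estimate_pve(b) for b in blocks if b.p >= 1}
    retained, report = qc_filter_genes(blocks, pves, config.qc)
    logger.info(
        "funnel: %d genes read -> %d with CpGs -> %d pass QC",
        n_read, len(blocks), len(retained),
    )
    return retained, report, surv


def _analyze_star(args):
    return analyze_gene(*args)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the full per-gene analysis and write results under ``config.outdir``.

    Writes results.tsv (versioned schema header), qc_report.tsv and
    intersections.tsv; returns the results frame. Rerunning the same config
    reproduces the outputs byte-identically.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks, report, surv = prepare_inputs(config)
    report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
    if not blocks:
        logger.warning("no genes passed QC; writing empty results")
        empty = pd.DataFrame(columns=["gene_id"])
        _write_results(empty, outdir)
        return empty

    tasks = [(b, surv, config) for b in blocks]
    if config.n_jobs > 1:
        with ProcessPoolExecutor(max_workers=config.n_jobs) as pool:
            records = list(pool.map(_analyze_star, tasks, chunksize=4))
    else:
        records = []
        for i, t in enumerate(tasks, 1):
            records.append(_analyze_star(t))
            if i % 100 == 0:
                logger.info("analyzed %d / %d genes", i, len(tasks))
    records = [r for r in records if r is not None]
    results = pd.DataFrame(records).sort_values("gene_id").reset_index(drop=True)

    for model in config.models:
        col = f"p_{model}"
        if col in results.columns:
            ok = results[col].notna()
            results[f"fdr_{model}"] = np.nan
            if ok.any():
                results.loc[ok, f"fdr_{model}"] = bh_fdr(results.loc[ok, col].to_numpy())
    ok = results["p_acat"].notna()
    results["fdr_acat"] = np.nan
    if ok.any():
        results.loc[ok, "fdr_acat"] = bh_fdr(results.loc[ok, "p_acat"].to_numpy())
    results["called"] = results["fdr_acat"] < config.fdr_threshold

    _write_results(results, outdir)
    _, intersections = call_significant(results, config.fdr_threshold, mode="combined")
    intersections.to_csv(outdir / "intersections.tsv", sep="\t", index=False)
    logger.info("results: %d genes tested, %d called at FDR < %g",
                len(results), int(results["called"].sum()), config.fdr_threshold)
    return results


def _write_results(results: pd.DataFrame, outdir: Path) -> None:
    path = outdir / "results.tsv"
    with open(path, "w") as fh:
        fh.write(f"# {RESULTS_SCHEMA}\n")
        results.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
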