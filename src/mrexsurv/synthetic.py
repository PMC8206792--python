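"""Synthetic datasets with the generative structure the method assumes.

Emulates a methylation/expression/survival cohort shaped like the cervical
tumor study the defaults are drawn from: n = 190 patients, ~26% deaths
(censoring target 0.74), follow-up on a months scale (exponential baseline
hazard 0.02/month, median ~35 months), three clinical covariates (age,
stage, tumor status), correlated CpG blocks per gene, expression = Mw + eps
with controllable sparsity and PVE, and proportional-hazards survival with
optional direct (pleiotropic) CpG effects. Every generated dataset carries
its generating truth so recovery can be scored without re-deriving it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    FeatureAnnotation,
    OmicsMatrix,
    SurvivalTable,
    write_bed6,
    write_omics_table,
    write_survival_table,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_methylation",
    "simulate_expression",
    "simulate_covariates",
    "simulate_survival",
    "make_fixture",
]

_GENE_SPACING = 100_000
_GENE_LENGTH = 10_000


@dataclass
class SimConfig:
    """Generating parameters; defaults emulate the study cohort."""

    n: int = 190
    genes: int = 50
    p_per_gene: int = 30
    cpg_corr: float = 0.5
    architecture: str = "sparse"  # or "polygenic"
    k_causal: int = 5
    pve: float = 0.3
    b: float = 0.0
    n_signal_genes: int = 0
    sigma_c2: float = 0.0
    covariate_effects: tuple = (0.3, 0.2, 0.2)  # age, stage, tumor_status
    baseline: tuple = ("exponential", 0.02)  # or ("weibull", shape, scale)
    censor_target: float = 0.74
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cpg_corr < 1:
            raise ValueError("cpg_corr must be in [0, 1)")
        if not 0 <= self.pve < 1:
            raise ValueError("pve must be in [0, 1); pve = 1 leaves no residual")
        if not 0 <= self.censor_target < 1:
            raise ValueError("censor_target must be in [0, 1)")
        if self.architecture not in ("sparse", "polygenic"):
            raise ValueError("architecture must be 'sparse' or 'polygenic'")


@dataclass
class SimTruth:
    """Generating parameters stored alongside each dataset."""

    w: dict[str, np.ndarray]
    b: dict[str, float]
    c: dict[str, np.ndarray]
    realized_pve: dict[str, float]
    realized_censoring: float = np.nan


def _standardize(block: np.ndarray) -> np.ndarray:
    return (block - block.mean(axis=0)) / block.std(axis=0, ddof=1)


def simulate_methylation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[OmicsMatrix, list[FeatureAnnotation], list[FeatureAnnotation]]:
    """Draw per-gene CpG blocks with exchangeable correlation, standardized.

    Genes are laid out on one synthetic chromosome far enough apart that
    block assembly with any promoter extension below the spacing reproduces
    the generated blocks exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    rho, p = config.cpg_corr, config.p_per_gene
    sample_ids = [f"S{i:04d}" for i in range(config.n)]
    blocks, genes, cpgs, cpg_ids = [], [], [], []
    for gi in range(config.genes):
        u = rng.standard_normal((config.n, 1))
        e = rng.standard_normal((config.n, p))
        block = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
        blocks.append(_standardize(block))
        start = 10_000 + gi * _GENE_SPACING
        end = start + _GENE_LENGTH
        gene_id = f"gene{gi:04d}"
        genes.append(FeatureAnnotation(gene_id, "chr1", start, end, "+", "gene"))
        pos = np.linspace(start, end, p).round().astype(int)
        pos = start + np.unique(pos - start)  # guard against rounding collisions
        assert pos.size == p, "CpG layout produced duplicate positions"
        for j, x in enumerate(pos):
            cid = f"cg{gi:04d}_{j:03d}"
            cpg_ids.append(cid)
            cpgs.append(FeatureAnnotation(cid, "chr1", int(x), int(x), "+", "cpg"))
    matrix = OmicsMatrix(sample_ids, cpg_ids, np.hstack(blocks))
    return matrix, genes, cpgs


def simulate_expression(
    M: np.ndarray,
    architecture: str = "sparse",
    pve: float = 0.3,
    rng: np.random.Generator | None = None,
    k_causal: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw G = Mw + eps with the requested architecture and variance split.

    Sparse: ``k_causal`` seeded nonzero weights; polygenic: all CpGs weighted.
    w is rescaled so the realized var(Mw) equals ``pve`` with residual
    variance 1 - pve, so var(Mw)/var(G) ~ pve.
    """
    rng = rng or np.random.default_rng(0)
    if not 0 <= pve < 1:
        raise ValueError("pve must be in [0, 1)")
    n, p = M.shape
    if pve == 0:
        return rng.standard_normal(n), np.zeros(p)
    if architecture == "sparse":
        w = np.zeros(p)
        pos = rng.choice(p, size=min(k_causal, p), replace=False)
        w[pos] = rng.standard_normal(pos.size)
    elif architecture == "polygenic":
        w = rng.standard_normal(p)
    else:
        raise ValueError("architecture must be 'sparse' or 'polygenic'")
    gv = M @ w
    w *= np.sqrt(pve / gv.var(ddof=1))
    eps = rng.standard_normal(n) * np.sqrt(1.0 - pve)
    return M @ w + eps, w


def simulate_covariates(n: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clinical covariates shaped like the cohort: age, stage (1-4), tumor status."""
    rng = rng or np.random.default_rng(0)
    age = np.clip(rng.normal(47.8, 13.0, n), 20, 81).round(1)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.574, 0.221, 0.153, 0.052])
    tumor = rng.binomial(1, 0.274, n)
    return pd.DataFrame({"age": age, "stage": stage.astype(float), "tumor_status": tumor.astype(float)})


def _censoring_horizon(T: np.ndarray, target: float) -> float:
    """Bisection on the uniform-censoring horizon tau so that the expected
    censored fraction E[P(C < T)] with C ~ U(0, tau) matches the target."""

    def expected(tau: float) -> float:
        return float(np.minimum(T / tau, 1.0).mean())

    lo, hi = T.min() * 1e-6, T.max() * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_survival(
    X: np.ndarray | pd.DataFrame | None,
    g_true: np.ndarray | None,
    M: np.ndarray | None,
    a=None,
    b: float = 0.0,
    c=None,
    baseline=("exponential", 0.02),
    censor_target: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_ids=None,
) -> SurvivalTable:
    """Event times from the proportional-hazards model by inverse transform.

    The linear predictor is X a + g_true * b + M c (any part may be None).
    Censoring is independent uniform on [0, tau] with tau calibrated by
    bisection so that the expected censored fraction matches
    ``censor_target``.
    """
    rng = rng or np.random.default_rng(0)
    if not 0 <= censor_target < 1:
        raise ValueError("censor_target must be in [0, 1)")
    parts = []
    cov_df = pd.DataFrame()
    if X is not None:
        if isinstance(X, pd.DataFrame):
            cov_df = X.reset_index(drop=True)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.atleast_2d(np.asarray(X, dtype=float))
            cov_df = pd.DataFrame(Xv, columns=[f"x{j}" for j in range(Xv.shape[1])])
        if a is None:
            raise ValueError("covariates supplied without effects a")
        # standardized-scale effects keep coefficients comparable across covariates
        Xs = (Xv - Xv.mean(axis=0)) / np.where(Xv.std(axis=0) > 0, Xv.std(axis=0), 1.0)
        parts.append(Xs @ np.asarray(a, dtype=float))
    if g_true is not None and b != 0.0:
        parts.append(b * np.asarray(g_true, dtype=float))
    if M is not None and c is not None:
        parts.append(np.asarray(M, dtype=float) @ np.asarray(c, dtype=float))
    n = None
    for src in (X, g_true, M):
        if src is not None:
            n = len(src)
            break
    if n is None:
        raise ValueError("at least one of X, g_true, M must be given")
    eta = np.sum(parts, axis=0) if parts else np.zeros(n)
    u = rng.uniform(size=n)
    kind = baseline[0]
    if kind == "exponential":
        lam0 = baseline[1]
        T = -np.log(u) / (lam0 * np.exp(eta))
    elif kind == "weibull":
        shape, scale = baseline[1], baseline[2]
        T = scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / shape)
    else:
        raise ValueError("baseline must be ('exponential', rate) or ('weibull', shape, scale)")
    if censor_target == 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        tau = _censoring_horizon(T, censor_target)
        C = rng.uniform(0, tau, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return SurvivalTable(list(sample_ids), time, event, cov_df)


def make_fixture(
    config: SimConfig, outdir, overwrite: bool = False
) -> tuple[dict[str, Path], SimTruth]:
    """Write a complete on-disk dataset in the formats the readers accept.

    Produces methylation.tsv, expression.tsv, survival.tsv, genes.bed,
    cpgs.bed, truth tables and a manifest; regeneration with the same config
    is byte-identical. The first ``n_signal_genes`` genes contribute
    b * g_true + M c to the log hazard.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    methyl, genes, cpgs = simulate_methylation(config, rng)
    p = config.p_per_gene
    expr_cols, truth = [], SimTruth({}, {}, {}, {})
    eta_g = np.zeros(config.n)
    signal_M, signal_c = [], []
    for gi, gene in enumerate(genes):
        block = methyl.values[:, gi * p:(gi + 1) * p]
        G, w = simulate_expression(block, config.architecture, config.pve, rng, config.k_causal)
        expr_cols.append(G)
        is_signal = gi < config.n_signal_genes
        b = config.b if is_signal else 0.0
        c = np.zeros(p)
        if is_signal and config.sigma_c2 > 0:
            c = rng.normal(0.0, np.sqrt(config.sigma_c2), p)
        truth.w[gene.feature_id] = w
        truth.b[gene.feature_id] = b
        truth.c[gene.feature_id] = c
        gv = block @ w
        denom = G.var(ddof=1)
        truth.realized_pve[gene.feature_id] = float(gv.var(ddof=1) / denom) if denom > 0 else 0.0
        if is_signal:
            eta_g = eta_g + b * gv
            if config.sigma_c2 > 0:
                signal_M.append(block)
                signal_c.append(c)
    expr = OmicsMatrix(methyl.sample_ids, [g.feature_id for g in genes],
                       np.column_stack(expr_cols))

    covariates = simulate_covariates(config.n, rng)
    surv = simulate_survival(
        covariates,
        eta_g,
        np.hstack(signal_M) if signal_M else None,
        a=config.covariate_effects,
        b=1.0,  # eta_g already carries the per-gene effects
        c=np.concatenate(signal_c) if signal_c else None,
        baseline=tuple(config.baseline),
        censor_target=config.censor_target,
        rng=rng,
        sample_ids=methyl.sample_ids,
    )
    truth.realized_censoring = float(1.0 - surv.event.mean())

    paths = {
        "methylation": outdir / "methylation.tsv",
        "expression": outdir / "expression.tsv",
        "survival": outdir / "survival.tsv",
        "genes_bed": outdir / "genes.bed",
        "cpgs_bed": outdir / "cpgs.bed",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_weights": outdir / "truth_weights.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    write_omics_table(methyl, paths["methylation"])
    write_omics_table(expr, paths["expression"])
    write_survival_table(surv, paths["survival"])
    write_bed6(genes, paths["genes_bed"])
    write_bed6(cpgs, paths["cpgs_bed"])

    pd.DataFrame(
        {
            "gene_id": [g.feature_id for g in genes],
            "b": [truth.b[g.feature_id] for g in genes],
            "realized_pve": [truth.realized_pve[g.feature_id] for g in genes],
        }
    ).to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.10g")
    rows = []
    for gi, gene in enumerate(genes):
        for j in range(p):
            rows.append(
                dict(gene_id=gene.feature_id, cpg_id=f"cg{gi:04d}_{j:03d}",
                     w=truth.w[gene.feature_id][j], c=truth.c[gene.feature_id][j])
            )
    pd.DataFrame(rows).to_csv(paths["truth_weights"], sep="\t", index=False,
                              float_format="%.10g")
    manifest = {"config": asdict(config), "realized_censoring": truth.realized_censoring}
    manifest["config"]["covariate_effects"] = list(config.covariate_effects)
    manifest["config"]["baseline"] = list(config.baseline)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths, truth
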