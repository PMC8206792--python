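"""Stage 1: per-gene CpG weight estimation and expression imputation.

Three built-in architectures for G = Mw + eps:

* ``lmm`` — ridge/BLUP weights w = (M'M + lambda I)^-1 M'G with the penalty
  lambda = p * sigma_e2 / sigma_g2 taken from the REML variance components of
  the CpG kernel (all CpGs receive weight);
* ``lasso`` — L1 penalty, lambda selected at minimum mean CV error;
* ``enet`` — mixed L1/L2 penalty with fixed mixing alpha (glmnet
  parameterization), CV-selected lambda.

The imputed, methylation-regulated expression ("MReX") is g_hat = M w_hat
(+ intercept); externally estimated weight vectors can be injected through
``PredictionFit`` so downstream stages work for any model set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import KFold

from .io import GeneBlock
from .qc import estimate_pve

__all__ = [
    "PredictionFit",
    "MrexVector",
    "BUILTIN_MODELS",
    "fit_weights",
    "cross_validated_r2",
    "impute_mrex",
]

BUILTIN_MODELS = ("lmm", "lasso", "enet")


@dataclass
class PredictionFit:
    """Estimated CpG weights for one gene under one prediction model."""

    gene_id: str
    model: str
    w_hat: np.ndarray
    intercept: float
    sigma_eps2: float
    cv_r2: float | None = None
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w_hat = np.asarray(self.w_hat, dtype=float)


@dataclass
class MrexVector:
    """Imputed methylation-regulated expression g_hat = M w_hat + intercept."""

    gene_id: str
    model: str
    g_hat: np.ndarray


def _ridge_lambda_from_reml(block: GeneBlock) -> tuple[float, dict]:
    """lambda = sigma_e2 / sigma_w2 with sigma_w2 = sigma_g2 / p under the
    MM'/p kernel scaling used by the REML screen."""
    est = estimate_pve(block)
    gamma = est.sigma_g2 / est.sigma_e2 if est.sigma_e2 > 0 else np.inf
    lam = block.p / max(gamma, 1e-12)
    return lam, {"sigma_g2": est.sigma_g2, "sigma_e2": est.sigma_e2, "pve": est.pve}


def _fit_lmm(block: GeneBlock, lam: float | None) -> PredictionFit:
    M, G = block.M, block.G
    extra: dict = {}
    if lam is None:
        lam, extra = _ridge_lambda_from_reml(block)
    Mc = M - M.mean(axis=0)
    Gc = G - G.mean()
    A = Mc.T @ Mc + lam * np.eye(block.p)
    w = np.linalg.solve(A, Mc.T @ Gc)
    intercept = float(G.mean() - M.mean(axis=0) @ w)
    resid = G - (M @ w + intercept)
    dof = max(block.n - 1, 1)
    return PredictionFit(
        gene_id=block.gene_id,
        model="lmm",
        w_hat=w,
        intercept=intercept,
        sigma_eps2=float(resid @ resid / dof),
        hyperparams={"lambda": float(lam), **extra},
    )


def _sklearn_estimator(model: str, lam: float | None, enet_alpha: float,
                       folds: int, seed: int, n: int):
    if lam is not None:
        if model == "lasso":
            return Lasso(alpha=lam, max_iter=50000, tol=1e-8)
        return ElasticNet(alpha=lam, l1_ratio=enet_alpha, max_iter=50000, tol=1e-8)
    if n < folds:
        raise ValueError(
            f"cross-validation infeasible: n={n} < folds={folds}; use a smaller k"
        )
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    if model == "lasso":
        return LassoCV(cv=cv, alphas=100, max_iter=50000, tol=1e-7)
    return ElasticNetCV(cv=cv, l1_ratio=enet_alpha, alphas=100, max_iter=50000, tol=1e-7)


def fit_weights(
    block: GeneBlock,
    model: str = "lmm",
    hyperparams: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> PredictionFit:
    """Estimate CpG effect sizes w_hat for one gene.

    ``hyperparams`` may fix the penalty (``lambda``) and, for enet, the mixing
    ``alpha`` (default 0.5); otherwise lambda comes from REML (lmm) or k-fold
    CV at minimum mean error (lasso/enet). The intercept is never penalized.
    """
    if model not in BUILTIN_MODELS:
        raise ValueError(f"unknown model {model!r}; built-ins are {BUILTIN_MODELS}")
    if block.p == 0:
        raise ValueError("cannot fit weights with zero CpGs")
    hp = dict(hyperparams or {})
    lam = hp.get("lambda")
    if model == "lmm":
        return _fit_lmm(block, lam)
    enet_alpha = float(hp.get("alpha", 0.5)) if model == "enet" else 1.0
    est = _sklearn_estimator(model, lam, enet_alpha, folds, seed, block.n)
    est.fit(block.M, block.G)
    w = np.asarray(est.coef_, dtype=float)
    intercept = float(est.intercept_)
    resid = block.G - (block.M @ w + intercept)
    out_hp = {"lambda": float(getattr(est, "alpha_", lam))}
    if model == "enet":
        out_hp["alpha"] = enet_alpha
    return PredictionFit(
        gene_id=block.gene_id,
        model=model,
        w_hat=w,
        intercept=intercept,
        sigma_eps2=float(resid @ resid / max(block.n - 1, 1)),
        hyperparams=out_hp,
    )


def cross_validated_r2(
    block: GeneBlock,
    model: str = "lmm",
    folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> float:
    """Out-of-fold R^2 = 1 - SSE/SST over concatenated held-out predictions.

    Fold assignment is seeded and deterministic; penalty selection for
    lasso/enet is re-done inside each training fold. May be negative.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(block.G)
    for train, test in kf.split(block.M):
        sub = GeneBlock(block.gene_id, block.G[train], block.M[train], block.cpg_ids)
        fit = fit_weights(sub, model, hyperparams=hyperparams, folds=folds, seed=seed)
        pred[test] = block.M[test] @ fit.w_hat + fit.intercept
    sse = float(np.sum((block.G - pred) ** 2))
    sst = float(np.sum((block.G - block.G.mean()) ** 2))
    return 1.0 - sse / sst


def impute_mrex(block: GeneBlock, fit: PredictionFit) -> MrexVector:
    """Impute expression from methylation: g_hat = M w_hat + intercept."""
    if fit.gene_id != block.gene_id:
        raise ValueError(f"fit is for {fit.gene_id}, block is {block.gene_id}")
    if fit.w_hat.shape != (block.p,):
        raise ValueError(
            f"weight length {fit.w_hat.shape[0]} does not match p={block.p}"
        )
    return MrexVector(block.gene_id, fit.model, block.M @ fit.w_hat + fit.intercept)
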