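"""Preprocessing and gene-level filtering.

Order of operations: median imputation, then inverse-normal transform of each
gene's expression and standardization of each CpG, then the variance-component
(PVE) screen. Genes enter the association stage only with at least
``min_cpgs`` CpGs in their window and a methylation PVE above ``min_pve``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GeneBlock, OmicsMatrix

logger = logging.getLogger("mrexsurv")

__all__ = [
    "QcConfig",
    "PveEstimate",
    "impute_median",
    "inverse_normal_transform",
    "standardize_features",
    "estimate_pve",
    "qc_filter_genes",
]


@dataclass
class QcConfig:
    """Thresholds for the preprocessing filters.

    max_missing_frac: features with a larger missing fraction are dropped
        before imputation (default 0.10).
    min_cpgs: minimum CpG count in the promoter + gene-body window (>= 10).
    min_pve: expression variance explained by the CpG kernel must exceed
        this fraction (strict inequality; default 0.01, i.e. a marginal
        methylation-expression correlation of about 10%).
    inverse_normal_offset: rank offset of the quantile transform, (r - offset)/n.
    """

    max_missing_frac: float = 0.10
    min_cpgs: int = 10
    min_pve: float = 0.01
    inverse_normal_offset: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must be in [0, 1)")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not 0 <= self.min_pve < 1:
            raise ValueError("min_pve must be in [0, 1)")


@dataclass
class PveEstimate:
    """REML variance components of G ~ N(mu, sigma_g2 * MM'/p + sigma_e2 * I)."""

    gene_id: str
    pve: float
    sigma_g2: float
    sigma_e2: float
    converged: bool = True
    boundary: bool = False


def impute_median(matrix: OmicsMatrix, max_missing_frac: float = 0.10) -> OmicsMatrix:
    """Replace missing entries by the per-feature median of observed values.

    Features whose missing fraction exceeds ``max_missing_frac`` (or that are
    entirely missing) are dropped and logged.
    """
    vals = matrix.values
    miss = np.isnan(vals)
    if not miss.any():
        return matrix
    frac = miss.mean(axis=0)
    keep = frac <= max_missing_frac
    all_missing = frac == 1.0
    if all_missing.any():
        logger.warning(
            "impute_median: %d features entirely missing, dropped", int(all_missing.sum())
        )
    keep &= ~all_missing
    dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    if dropped:
        logger.info(
            "impute_median: dropped %d features with missing fraction > %.3g",
            len(dropped), max_missing_frac,
        )
    vals = vals[:, keep].copy()
    med = np.nanmedian(vals, axis=0)
    idx = np.where(np.isnan(vals))
    vals[idx] = med[idx[1]]
    return OmicsMatrix(
        list(matrix.sample_ids),
        [f for f, k in zip(matrix.feature_ids, keep) if k],
        vals,
    )


def inverse_normal_transform(vector, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal (quantile) transform.

    Value with (average, for ties) rank r maps to Phi^-1((r - offset)/n), so
    the output follows a standard normal distribution and is monotone in the
    input. Undefined for constant input or n < 3.
    """
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("inverse_normal_transform needs a 1-D vector with n >= 3")
    if np.isnan(v).any():
        raise ValueError("impute before transforming")
    if np.ptp(v) == 0:
        raise ValueError("inverse_normal_transform undefined for constant input")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / v.size)


def standardize_features(matrix: OmicsMatrix) -> OmicsMatrix:
    """Center and scale each feature to mean 0, sample variance 1 (ddof=1).

    Zero-variance features are dropped; it is an error for all of them to be.
    """
    vals = matrix.values
    if vals.shape[0] < 2:
        raise ValueError("standardization needs n >= 2")
    if np.isnan(vals).any():
        raise ValueError("impute before standardizing")
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features have zero variance")
    if (~keep).any():
        logger.info("standardize_features: dropped %d zero-variance features", int((~keep).sum()))
    out = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]
    return OmicsMatrix(
        list(matrix.sample_ids),
        [f for f, k in zip(matrix.feature_ids, keep) if k],
        out,
    )


def _reml_terms(y: np.ndarray, M: np.ndarray):
    """Eigen-split quantities for the kernel K = MM'/p used by the REML profile."""
    n, p = M.shape
    # economy SVD: K has eigenvalues s^2/p on the column space of M, 0 elsewhere
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    lam = s**2 / p
    X = np.ones((n, 1))
    z = U.T @ y
    zx = (U.T @ X)[:, 0]
    y_perp2 = float(y @ y - z @ z)
    x_perp2 = float(n - zx @ zx)
    xy_perp = float(X[:, 0] @ y - zx @ z)
    return lam, z, zx, max(y_perp2, 0.0), max(x_perp2, 0.0), xy_perp, n


def _reml_profile(log_ratio: float, terms) -> tuple[float, float]:
    """Profiled REML log-likelihood (up to a constant) at variance ratio
    gamma = sigma_g2/sigma_e2 = exp(log_ratio); returns (loglik, sigma_e2_hat)."""
    lam, z, zx, y_perp2, x_perp2, xy_perp, n = terms
    gamma = np.exp(log_ratio)
    d = gamma * lam + 1.0
    yVy = float(z**2 @ (1.0 / d)) + y_perp2
    xVx = float(zx**2 @ (1.0 / d)) + x_perp2
    xVy = float((zx * z) @ (1.0 / d)) + xy_perp
    ypy = yVy - xVy**2 / xVx
    if ypy <= 0:
        return -np.inf, 0.0
    sigma_e2 = ypy / (n - 1)
    logdet = float(np.log(d).sum())  # complement eigenvalues are 1
    ll = -0.5 * (logdet + np.log(xVx) + (n - 1) * np.log(ypy))
    return ll, sigma_e2


def estimate_pve(
    block: GeneBlock,
    gene_id: str | None = None,
    bounds: tuple[float, float] = (-12.0, 12.0),
    tol: float = 1e-8,
) -> PveEstimate:
    """REML estimate of the expression variance explained by the CpG kernel.

    Fits G ~ N(mu*1, sigma_g2 * MM'/p + sigma_e2 * I) by a bounded 1-D Brent
    search over log(sigma_g2/sigma_e2), and returns
    pve = sigma_g2 / (sigma_g2 + sigma_e2) clipped to [0, 1].
    """
    terms = _reml_terms(block.G, block.M)
    res = optimize.minimize_scalar(
        lambda t: -_reml_profile(t, terms)[0],
        bounds=bounds,
        method="bounded",
        options={"xatol": tol},
    )
    log_ratio = float(res.x)
    ll, sigma_e2 = _reml_profile(log_ratio, terms)
    gamma = np.exp(log_ratio)
    # prefer an exact boundary when the criterion is monotone toward it
    for edge in bounds:
        ll_edge, se_edge = _reml_profile(edge, terms)
        if ll_edge > ll:
            log_ratio, ll, sigma_e2, gamma = edge, ll_edge, se_edge, np.exp(edge)
    boundary = min(log_ratio - bounds[0], bounds[1] - log_ratio) < 1e-3
    sigma_g2 = gamma * sigma_e2
    pve = float(np.clip(sigma_g2 / (sigma_g2 + sigma_e2), 0.0, 1.0))
    if boundary:
        logger.debug("estimate_pve(%s): optimum at search bound", gene_id or block.gene_id)
    return PveEstimate(
        gene_id=gene_id or block.gene_id,
        pve=pve,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        converged=bool(res.success),
        boundary=bool(boundary),
    )


def qc_filter_genes(
    blocks: list[GeneBlock],
    pve_estimates: dict[str, PveEstimate] | list[PveEstimate],
    config: QcConfig | None = None,
) -> tuple[list[GeneBlock], pd.DataFrame]:
    """Apply the two gene-level filters: p >= min_cpgs and pve > min_pve.

    Returns the retained blocks and a report frame with one row per gene
    (gene_id, n, p, pve, retained, reason). Idempotent.
    """
    config = config or QcConfig()
    if not isinstance(pve_estimates, dict):
        pve_estimates = {e.gene_id: e for e in pve_estimates}
    retained: list[GeneBlock] = []
    rows = []
    for block in blocks:
        est = pve_estimates.get(block.gene_id)
        pve = est.pve if est is not None else np.nan
        if block.p < config.min_cpgs:
            reason = "cpg_count"
        elif est is None:
            reason = "no_pve_estimate"
        elif not pve > config.min_pve:
            reason = "pve"
        else:
            reason = ""
            retained.append(block)
        rows.append(
            dict(gene_id=block.gene_id, n=block.n, p=block.p, pve=pve,
                 retained=reason == "", reason=reason)
        )
    report = pd.DataFrame(rows, columns=["gene_id", "n", "p", "pve", "retained", "reason"])
    logger.info("qc_filter_genes: retained %d / %d genes", len(retained), len(blocks))
    return retained, report
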