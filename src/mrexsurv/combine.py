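"""Aggregation of per-gene p-values across prediction models.

The aggregated Cauchy association test (ACAT) maps each p-value to the Cauchy
scale, T = sum_k w_k tan((1/2 - p_k) pi), and back:
p = 1/2 - arctan(T / sum_k w_k) / pi. It stays calibrated under the strong
positive dependence expected when the same survival data are tested with
several prediction models. Gene calling applies Benjamini-Hochberg FDR either
per model or on the combined ACAT p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["AcatResult", "acat_combine", "bh_fdr", "call_significant"]

_P_FLOOR = 1e-15


@dataclass
class AcatResult:
    t_stat: float
    p_combined: float


def acat_combine(p_values, weights=None) -> AcatResult:
    """Combine K >= 1 dependent p-values with the Cauchy combination test.

    Weights need not be normalized (they are rescaled to sum to one; equal by
    default). For p below 1e-15 the tangent term is replaced by its asymptote
    1/(p pi); p-values at 1 are clipped just below it.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("acat_combine needs at least one p-value")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != p.shape:
            raise ValueError("weights must match p-values in length")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if w.sum() <= 0:
            raise ValueError("at least one weight must be positive")
        w = w / w.sum()
    tiny = p < _P_FLOOR
    pc = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    terms = np.tan((0.5 - pc) * np.pi)
    terms[tiny] = 1.0 / (p[tiny] * np.pi)
    t = float(w @ terms)
    if t > 1e15:  # arctan saturates; use the Cauchy tail asymptote
        p_comb = 1.0 / (t * np.pi)
    else:
        p_comb = 0.5 - np.arctan(t) / np.pi
    p_comb = float(np.clip(p_comb, np.nextafter(0, 1), 1.0 - _P_FLOOR))
    return AcatResult(t_stat=t, p_combined=p_comb)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    records: pd.DataFrame,
    threshold: float = 0.05,
    mode: str = "combined",
) -> tuple[set, pd.DataFrame]:
    """Call genes at FDR < threshold and tabulate cross-model intersections.

    ``records`` must have a ``gene_id`` column, per-model ``p_<model>``
    columns and (for the combined mode) ``p_acat``. FDR is computed within
    each p-value column across genes. Returns the called gene set for the
    requested mode and an UpSet-style table counting genes in every
    intersection of the per-model call sets.
    """
    if mode not in ("combined", "per_model"):
        raise ValueError("mode must be 'combined' or 'per_model'")
    models = [c[2:] for c in records.columns if c.startswith("p_") and c != "p_acat"]
    call_sets: dict[str, set] = {}
    for model in models:
        p = records[f"p_{model}"]
        ok = p.notna()
        fdr = pd.Series(np.nan, index=records.index)
        if ok.any():
            fdr[ok] = bh_fdr(p[ok].to_numpy())
        call_sets[model] = set(records.loc[fdr < threshold, "gene_id"])
    if mode == "combined":
        if "p_acat" not in records.columns:
            raise ValueError("combined mode needs a p_acat column")
        ok = records["p_acat"].notna()
        fdr = pd.Series(np.nan, index=records.index)
        if ok.any():
            fdr[ok] = bh_fdr(records.loc[ok, "p_acat"].to_numpy())
        called = set(records.loc[fdr < threshold, "gene_id"])
    else:
        called = set().union(*call_sets.values()) if call_sets else set()
    rows = []
    for k in range(1, len(models) + 1):
        for combo in combinations(models, k):
            inter = set.intersection(*(call_sets[m] for m in combo))
            rows.append({"models": "+".join(combo), "degree": k, "n_genes": len(inter)})
    table = pd.DataFrame(rows, columns=["models", "degree", "n_genes"])
    return called, table
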