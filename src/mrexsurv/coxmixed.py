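"""Stage 2: Cox proportional hazards with a fixed MReX effect and Gaussian
random CpG effects ("coxlmm").

The hazard is h(t | X, g_hat, M) = h0(t) exp(X a + g_hat b + M c) with
c ~ N(0, sigma_c2 I). For fixed sigma_c2 the penalized partial log-likelihood
l(a, b, c) - c'c / (2 sigma_c2) is maximized by Newton-Raphson with
step-halving; sigma_c2 itself is chosen by maximizing the Laplace
approximation of the integrated partial likelihood (a bounded Brent search on
log sigma_c2). The MReX effect b is tested with a Wald statistic
z = b_hat / sqrt(var(b_hat)), var(b_hat) taken from the inverse of the full
penalized information. First-stage weights are treated as fixed (no
measurement error), matching the one-sample two-stage design.

Ties are handled by the Efron correction by default (Breslow optional); the
baseline hazard is profiled out and only optionally recovered (Breslow
estimator) after the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import SurvivalTable
from .prediction import MrexVector

logger = logging.getLogger("mrexsurv")

__all__ = [
    "CoxFit",
    "CoxMixedFit",
    "WaldResult",
    "CoxMixedConfig",
    "cox_partial_loglik",
    "fit_cox",
    "fit_cox_mixed",
    "wald_test",
    "breslow_baseline",
]

#: infinity-norm bound on coefficients (standardized inputs) beyond which the
#: partial likelihood is treated as monotone (perfect separation in risk sets)
MONOTONE_BOUND = 15.0


@dataclass
class CoxMixedConfig:
    ties: str = "efron"
    max_inner_iter: int = 50
    inner_tol: float = 1e-8
    log_sigma_bounds: tuple[float, float] = (-10.0, 5.0)
    outer_tol: float = 1e-6


@dataclass
class CoxFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    monotone: bool
    n_events: int


@dataclass
class CoxMixedFit:
    """Fitted coxlmm: fixed covariate effects a, MReX effect b, posterior-mode
    random CpG effects c, and the Laplace-estimated variance sigma_c2."""

    a_hat: np.ndarray
    b_hat: float
    c_hat: np.ndarray
    sigma_c2: float
    var_b: float
    loglik_marginal: float
    converged: bool
    n_events: int
    monotone: bool = False
    baseline: np.ndarray | None = None  # (time, cumulative hazard) pairs


@dataclass
class WaldResult:
    z: float
    p_value: float
    effect: float
    se: float


class _CoxData:
    """Sorted survival data with precomputed risk-set/tie bookkeeping."""

    def __init__(self, surv: SurvivalTable, design: np.ndarray, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        design = np.atleast_2d(np.asarray(design, dtype=float))
        if design.shape[0] != surv.n:
            raise ValueError("design rows must match survival samples")
        if surv.n_events < 1:
            raise ValueError("partial likelihood undefined without events")
        order = np.argsort(surv.time, kind="stable")
        self.t = surv.time[order]
        self.e = surv.event[order]
        self.Z = design[order]
        self.n, self.q = self.Z.shape
        self.ties = ties
        ev = np.flatnonzero(self.e == 1)
        self.event_pos = ev
        ut, starts = np.unique(self.t[ev], return_index=True)
        self.group_starts = starts              # into the event list
        self.group_first = np.searchsorted(self.t, ut, side="left")
        d = np.diff(np.append(starts, ev.size))  # tied-event counts per group
        self.d = d
        self.slot_group = np.repeat(np.arange(ut.size), d)
        # Efron fraction j/d for slot j within its tie group; 0 for Breslow
        j = np.arange(ev.size) - starts[self.slot_group]
        self.frac = (j / d[self.slot_group]) if ties == "efron" else np.zeros(ev.size)
        # last tie group whose risk set each sorted subject belongs to
        self.subject_group = np.searchsorted(self.group_first, np.arange(self.n),
                                             side="right") - 1

    def _suffix_group_sums(self, arr: np.ndarray) -> np.ndarray:
        """Risk-set sums at each tie group's first index via segment reduceat
        + reverse cumulative sum (entries before the first event time never
        enter a risk set)."""
        seg = np.add.reduceat(arr, self.group_first, axis=0)
        return np.cumsum(seg[::-1], axis=0)[::-1]

    def loglik_grad_hess(self, beta: np.ndarray, want: int = 2):
        """Partial log-likelihood and, per ``want``, its gradient and Hessian."""
        beta = np.asarray(beta, dtype=float)
        eta = self.Z @ beta
        shift = eta.max() if eta.size else 0.0
        r = np.exp(eta - shift)
        ev, g, f = self.event_pos, self.slot_group, self.frac
        r_e = r[ev]
        Z_e = self.Z[ev]
        S0 = self._suffix_group_sums(r)
        s0 = np.add.reduceat(r_e, self.group_starts)
        denom = S0[g] - f * s0[g]
        ll = float((eta[ev] - shift).sum() - np.log(denom).sum())
        if want == 0:
            return ll, None, None
        S1 = self._suffix_group_sums(r[:, None] * self.Z)
        s1 = np.add.reduceat(r_e[:, None] * Z_e, self.group_starts, axis=0)
        num = S1[g] - f[:, None] * s1[g]          # (E, q)
        mean = num / denom[:, None]
        grad = Z_e.sum(axis=0) - mean.sum(axis=0)
        if want == 1:
            return ll, grad, None
        # sum_slots S2_slot/denom_slot rewritten subject-wise: subject i carries
        # weight r_i * (sum of 1/denom over the slots whose risk set holds i,
        # with the Efron fraction removed for its own tie group)
        inv_denom = 1.0 / denom
        prefix = np.cumsum(np.add.reduceat(inv_denom, self.group_starts))
        A = np.where(self.subject_group >= 0,
                     prefix[np.maximum(self.subject_group, 0)], 0.0)
        if self.ties == "efron":
            own = np.add.reduceat(f * inv_denom, self.group_starts)
            A[ev] -= own[g]
        hess = -(self.Z * (r * A)[:, None]).T @ self.Z + mean.T @ mean
        return ll, grad, hess


def cox_partial_loglik(
    beta, design, surv: SurvivalTable, ties: str = "efron"
) -> float:
    """Cox partial log-likelihood at ``beta`` (baseline hazard profiled out)."""
    data = _CoxData(surv, design, ties)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.q,):
        raise ValueError(f"beta length {beta.shape} does not match {data.q} columns")
    return data.loglik_grad_hess(beta, want=0)[0]


def _newton(data: _CoxData, penalty_diag: np.ndarray | None, init=None,
            max_iter: int = 50, tol: float = 1e-8):
    """Maximize the (optionally L2-penalized) partial log-likelihood.

    Step-halving enforces monotone increase of the objective; returns
    (beta, objective, neg_hessian_of_objective, converged, monotone_flag).
    """
    q = data.q
    beta = np.zeros(q) if init is None else np.asarray(init, dtype=float).copy()
    P = np.zeros(q) if penalty_diag is None else penalty_diag

    def objective(b):
        ll, grad, hess = data.loglik_grad_hess(b)
        obj = ll - 0.5 * float(P @ b**2)
        grad = grad - P * b
        hess = hess - np.diag(P)
        return obj, grad, hess

    obj, grad, hess = objective(beta)
    converged = False
    monotone = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_beta, new = beta + step, None
        for _ in range(30):  # step-halving
            cand, cg, ch = objective(new_beta)
            if np.isfinite(cand) and cand >= obj - 1e-12:
                new = (cand, cg, ch)
                break
            step /= 2.0
            new_beta = beta + step
        if new is None:
            break
        delta = new[0] - obj
        beta, (obj, grad, hess) = new_beta, new
        if np.max(np.abs(beta)) > MONOTONE_BOUND:
            monotone = True
            break
        if abs(delta) <= tol * (abs(obj) + tol):
            converged = True
            break
    return beta, obj, -hess, converged, monotone


def fit_cox(
    surv: SurvivalTable,
    design: np.ndarray,
    ties: str = "efron",
    init=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Maximum partial likelihood Cox fit by Newton-Raphson.

    A monotone likelihood (perfect separation in risk sets) is detected when
    the coefficient infinity-norm exceeds the bound and flagged, with the last
    iterate returned.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.ndim == 2 and design.shape[0] != surv.n and design.shape[1] == surv.n:
        design = design.T
    if surv.n_events < 2:
        raise ValueError("fit_cox needs at least two events")
    if design.shape[1] and (design.std(axis=0) == 0).any():
        raise ValueError("design contains constant columns")
    data = _CoxData(surv, design, ties)
    beta, ll, info, converged, monotone = _newton(data, None, init, max_iter, tol)
    if monotone:
        logger.warning("fit_cox: monotone likelihood detected (|beta| > %.0f)", MONOTONE_BOUND)
    cov = np.linalg.pinv(info) if monotone else np.linalg.inv(info)
    return CoxFit(beta, cov, ll, converged and not monotone, monotone, surv.n_events)


def _laplace_objective(data: _CoxData, p: int, sigma_c2: float, init,
                       max_iter: int, tol: float):
    """Laplace-approximated integrated partial log-likelihood at sigma_c2."""
    q = data.q
    P = np.zeros(q)
    P[q - p:] = 1.0 / sigma_c2
    beta, obj, pen_info, converged, monotone = _newton(data, P, init, max_iter, tol)
    # obj = l(theta) - c'c/(2 s2); Laplace adds -(p/2) log s2 - 0.5 logdet(I_cc + I/s2)
    cc = pen_info[q - p:, q - p:]
    sign, logdet = np.linalg.slogdet(cc)
    if sign <= 0:
        return -np.inf, beta, pen_info, converged, monotone
    marg = obj - 0.5 * p * np.log(sigma_c2) - 0.5 * logdet
    return marg, beta, pen_info, converged, monotone


def fit_cox_mixed(
    surv: SurvivalTable,
    X: np.ndarray | None,
    g_hat,
    M: np.ndarray | None,
    init=None,
    config: CoxMixedConfig | None = None,
    sigma_c2: float | None = None,
    with_baseline: bool = False,
) -> CoxMixedFit:
    """Fit the Cox mixed-effects model by penalized Newton + Laplace search.

    ``X`` (n x m fixed covariates) and ``M`` (n x p standardized CpGs) may be
    None/empty; with p = 0 the model reduces exactly to the plain Cox fit on
    (X, g_hat). ``sigma_c2`` may be fixed (e.g. for diagnostics); otherwise it
    is estimated on a bounded log grid by Brent search, with the boundary
    sigma_c2 -> 0 reported as 0.
    """
    config = config or CoxMixedConfig()
    if isinstance(g_hat, MrexVector):
        g_hat = g_hat.g_hat
    g = np.asarray(g_hat, dtype=float).reshape(-1)
    n = g.shape[0]
    X = np.empty((n, 0)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n and X.shape[1] == n:
        X = X.T
    M = np.empty((n, 0)) if M is None else np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != n and M.shape[1] == n:
        M = M.T
    m, p = X.shape[1], M.shape[1]
    if surv.n_events < 2:
        raise ValueError("fit_cox_mixed needs at least two events")
    Z = np.hstack([X, g[:, None], M])
    b_idx = m

    if p == 0:
        fit = fit_cox(surv, Z, ties=config.ties, init=init,
                      max_iter=config.max_inner_iter, tol=config.inner_tol)
        return CoxMixedFit(
            a_hat=fit.beta[:m], b_hat=float(fit.beta[b_idx]), c_hat=np.empty(0),
            sigma_c2=0.0, var_b=float(fit.cov[b_idx, b_idx]),
            loglik_marginal=fit.loglik, converged=fit.converged,
            n_events=fit.n_events, monotone=fit.monotone,
            baseline=breslow_baseline(surv, Z, fit.beta) if with_baseline else None,
        )

    data = _CoxData(surv, Z, config.ties)
    state: dict = {"theta": init}

    def neg_marginal(log_s2: float) -> float:
        marg, beta, *_ = _laplace_objective(
            data, p, float(np.exp(log_s2)), state["theta"],
            config.max_inner_iter, config.inner_tol,
        )
        state["theta"] = beta  # warm start across outer evaluations
        return -marg

    if sigma_c2 is not None:
        s2 = float(sigma_c2)
        boundary = s2 <= 0
    else:
        lo, hi = config.log_sigma_bounds
        res = optimize.minimize_scalar(
            neg_marginal, bounds=(lo, hi), method="bounded",
            options={"xatol": config.outer_tol},
        )
        boundary = res.x - lo < 1e-2 and neg_marginal(lo) <= res.fun + 1e-6
        s2 = 0.0 if boundary else float(np.exp(res.x))

    if boundary or s2 == 0.0:
        # sigma_c2 at the zero boundary: c == 0 and the model is plain Cox
        sub = fit_cox_mixed(surv, X, g, None, init=None, config=config,
                            with_baseline=with_baseline)
        return CoxMixedFit(
            a_hat=sub.a_hat, b_hat=sub.b_hat, c_hat=np.zeros(p), sigma_c2=0.0,
            var_b=sub.var_b, loglik_marginal=sub.loglik_marginal,
            converged=sub.converged, n_events=sub.n_events,
            monotone=sub.monotone, baseline=sub.baseline,
        )

    marg, beta, pen_info, converged, monotone = _laplace_objective(
        data, p, s2, state["theta"], config.max_inner_iter, config.inner_tol
    )
    cov = np.linalg.pinv(pen_info) if monotone else np.linalg.inv(pen_info)
    if monotone:
        logger.warning("fit_cox_mixed: monotone likelihood detected")
    return CoxMixedFit(
        a_hat=beta[:m], b_hat=float(beta[b_idx]), c_hat=beta[m + 1:],
        sigma_c2=s2, var_b=float(cov[b_idx, b_idx]), loglik_marginal=float(marg),
        converged=converged and not monotone, n_events=surv.n_events,
        monotone=monotone,
        baseline=breslow_baseline(surv, Z, beta) if with_baseline else None,
    )


def wald_test(fit: CoxMixedFit | CoxFit, index: int | None = None) -> WaldResult:
    """Two-sided Wald test of the MReX effect, z = b_hat / sqrt(var(b_hat))."""
    if isinstance(fit, CoxMixedFit):
        effect, var = fit.b_hat, fit.var_b
    else:
        i = 0 if index is None else index
        effect, var = float(fit.beta[i]), float(fit.cov[i, i])
    if not np.isfinite(var) or var <= 0:
        raise ValueError("degenerate information: var(b_hat) <= 0")
    se = float(np.sqrt(var))
    z = effect / se
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    return WaldResult(z=float(z), p_value=max(p, np.nextafter(0, 1)), effect=effect, se=se)


def breslow_baseline(surv: SurvivalTable, design: np.ndarray, beta) -> np.ndarray:
    """Breslow estimate of the cumulative baseline hazard H0(t) at event times.

    Returns an array of (time, H0) rows.
    """
    data = _CoxData(surv, design, ties="breslow")
    r = np.exp(data.Z @ np.asarray(beta, dtype=float))
    S0 = data._suffix_group_sums(r)
    increments = data.d / S0
    times = data.t[data.group_first]
    return np.column_stack([times, np.cumsum(increments)])
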