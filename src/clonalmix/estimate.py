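"""Estimators for the clonal-relatedness mixture model.

Two routes to the same observed-data likelihood:

* :func:`fit_onestep` — direct box-constrained quasi-Newton (L-BFGS-B)
  maximization of the marginal likelihood in (pi, mu, sigma). Fast, but in
  sparse datasets the clonal-proportion estimate not uncommonly lands exactly
  on the boundary 0 or 1, which forces every case's posterior clonality
  probability to 0 or 1.
* :func:`fit_em` — an EM algorithm over the latent clonality indicator C_j
  and signal xi_j. The E-step computes, per case, the posterior probability
  of clonality and the posterior moments of the transformed signal; the
  M-step has closed forms (weighted mean for pi, weighted normal moments for
  mu and sigma). EM reaches a boundary only if every case's posterior weight
  does, which in practice rescues most of the one-step boundary failures.

Fitting is deterministic: no randomness enters either estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import (
    SIGMA_MIN,
    CasePair,
    ModelParams,
    QuadratureGrid,
    build_grid,
    case_loglik_independent,
    xi_from_u,
)

__all__ = [
    "CasePosterior",
    "FitResult",
    "DEFAULT_INIT",
    "MULTISTART_PI0",
    "BOUNDARY_TOL",
    "e_step",
    "m_step",
    "fit_em",
    "fit_onestep",
    "posterior_clonality",
]

logger = logging.getLogger(__name__)

#: Default starting point (the intermediate built-in signal scenario).
DEFAULT_INIT = ModelParams(pi=0.5, mu=-1.0, sigma=1.0)
#: Clonal-proportion starts used when ``multistart=True``.
MULTISTART_PI0 = (0.1, 0.3, 0.5, 0.7, 0.9)
#: Proximity to 0/1 at which a fitted clonal proportion counts as boundary.
BOUNDARY_TOL = 1e-8

_BOUNDS = ((0.0, 1.0), (-10.0, 10.0), (SIGMA_MIN, 10.0))


@dataclass(frozen=True)
class CasePosterior:
    """E-step summary for one case at the current parameters.

    ``w`` is P(C_j = 1 | Y_j, params); ``m1`` and ``m2`` are the posterior
    mean and second moment of the transformed signal u_j given the case is
    clonal (they depend on the data through the clonal likelihood only, so
    they are well defined even when ``w`` is 0 or 1).
    """

    case_id: str
    w: float
    m1: float
    m2: float

    @property
    def variance(self) -> float:
        return self.m2 - self.m1**2


@dataclass
class FitResult:
    """Outcome of one fit: estimates, trajectory, flags, posteriors."""

    params: ModelParams
    loglik: float
    method: str
    converged: bool
    n_iter: int
    boundary: bool
    loglik_trace: list[float] = field(default_factory=list)
    posteriors: list[CasePosterior] = field(default_factory=list)
    message: str = ""

    @property
    def posterior_w(self) -> np.ndarray:
        return np.array([p.w for p in self.posteriors])


class _CompiledDataset:
    """Flat arrays over all loci for vectorized likelihood evaluation.

    The per-locus log-kernels for all cases are computed as one (K, L)
    matrix over the quadrature nodes and summed into per-case log-likelihoods
    with a single matrix product against a loci-to-case indicator.
    """

    def __init__(self, cases: Sequence[CasePair]):
        if len(cases) == 0:
            raise ValueError("dataset is empty: no cases to fit")
        self.cases = list(cases)
        self.n = len(cases)
        p, shared, case_col = [], [], []
        for j, case in enumerate(cases):
            for locus in case.loci:
                p.append(locus.p)
                shared.append(locus.shared)
                case_col.append(j)
        self.p = np.asarray(p, dtype=float)
        self.shared = np.asarray(shared, dtype=bool)
        indic = np.zeros((len(p), self.n))
        if len(p):
            indic[np.arange(len(p)), case_col] = 1.0
        self._indic = indic
        self.log_indep = np.array(
            [case_loglik_independent(c) for c in cases], dtype=float
        )

    def clonal_loglik_nodes(self, grid: QuadratureGrid) -> np.ndarray:
        """(K, n) matrix of log P(Y_j | xi(u_k), C_j = 1)."""
        if self.p.size == 0:
            return np.zeros((grid.k, self.n))
        u = grid.nodes
        xi = xi_from_u(u)[:, None]
        p = self.p[None, :]
        logden = np.log(2.0 - p - xi * (1.0 - p))
        lognum = np.empty_like(logden)
        s = self.shared
        if s.any():
            lognum[:, s] = np.log(p[:, s] + xi * (1.0 - p[:, s]))
        if (~s).any():
            log1m_xi = -np.exp(u)[:, None]  # log(1-xi) without cancellation
            lognum[:, ~s] = (
                np.log(2.0) + log1m_xi + np.log1p(-p[:, ~s])
            )
        return (lognum - logden) @ self._indic

    def marginal_loglik(self, params: ModelParams, grid: QuadratureGrid) -> float:
        """Observed-data log-likelihood at ``params``."""
        if params.pi == 0.0:
            return float(self.log_indep.sum())
        log_m = logsumexp(
            grid.log_weights[:, None] + self.clonal_loglik_nodes(grid), axis=0
        )
        if params.pi == 1.0:
            return float(log_m.sum())
        per_case = np.logaddexp(
            np.log(params.pi) + log_m,
            np.log1p(-params.pi) + self.log_indep,
        )
        return float(per_case.sum())


def _compile(dataset) -> _CompiledDataset:
    if isinstance(dataset, _CompiledDataset):
        return dataset
    return _CompiledDataset(dataset)


def _e_step_arrays(
    compiled: _CompiledDataset, params: ModelParams, grid_k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(log_m, w, m1, m2) arrays over cases; one likelihood-matrix build."""
    grid = build_grid(params, grid_k)
    terms = grid.log_weights[:, None] + compiled.clonal_loglik_nodes(grid)
    log_m = logsumexp(terms, axis=0)
    # posterior over nodes given clonal
    alpha = np.exp(terms - log_m[None, :])
    m1 = alpha.T @ grid.nodes
    m2 = alpha.T @ grid.nodes**2
    if params.pi == 0.0:
        w = np.zeros(compiled.n)
    elif params.pi == 1.0:
        w = np.ones(compiled.n)
    else:
        a = np.log(params.pi) + log_m
        b = np.log1p(-params.pi) + compiled.log_indep
        w = np.exp(a - np.logaddexp(a, b))
    return log_m, w, m1, m2


def _loglik_from_logm(
    compiled: _CompiledDataset, params: ModelParams, log_m: np.ndarray
) -> float:
    if params.pi == 0.0:
        return float(compiled.log_indep.sum())
    if params.pi == 1.0:
        return float(log_m.sum())
    per_case = np.logaddexp(
        np.log(params.pi) + log_m,
        np.log1p(-params.pi) + compiled.log_indep,
    )
    return float(per_case.sum())


def e_step(
    dataset: Sequence[CasePair],
    params: ModelParams,
    grid_k: int = 64,
) -> list[CasePosterior]:
    """Posterior clonality probabilities and signal moments per case.

    ``w_j = pi M_j / (pi M_j + (1 - pi) I_j)`` with ``M_j`` the clonal
    likelihood marginalized over the signal and ``I_j`` the independent-case
    likelihood; ``m1, m2`` are quadrature expectations of u and u^2 under the
    posterior density proportional to P(Y_j | xi(u), C=1) N(u; mu, sigma).
    At ``pi`` exactly 0 or 1 the weights are the forced constants.
    """
    compiled = _compile(dataset)
    _, w, m1, m2 = _e_step_arrays(compiled, params, grid_k)
    return [
        CasePosterior(case_id=c.case_id, w=float(wj), m1=float(a1), m2=float(a2))
        for c, wj, a1, a2 in zip(compiled.cases, w, m1, m2)
    ]


def m_step(
    posteriors: Sequence[CasePosterior],
    current: ModelParams,
    sigma_min: float = SIGMA_MIN,
) -> ModelParams:
    """Closed-form maximizer of the expected complete-data log-likelihood.

    pi is the mean posterior weight; mu and sigma^2 are the weight-averaged
    posterior moments of the transformed signal. If no case carries weight
    the signal parameters are left at their current values (degenerate
    branch: the expected log-likelihood is flat in them).
    """
    if len(posteriors) == 0:
        raise ValueError("m_step needs at least one posterior")
    w = np.array([p.w for p in posteriors])
    m1 = np.array([p.m1 for p in posteriors])
    m2 = np.array([p.m2 for p in posteriors])
    return _m_step_arrays(w, m1, m2, current, sigma_min)


def _m_step_arrays(
    w: np.ndarray,
    m1: np.ndarray,
    m2: np.ndarray,
    current: ModelParams,
    sigma_min: float = SIGMA_MIN,
) -> ModelParams:
    pi = float(w.mean())
    sw = w.sum()
    if sw == 0.0:
        logger.warning(
            "all posterior clonality weights are zero; keeping current "
            "signal parameters (mu=%.4g, sigma=%.4g)", current.mu, current.sigma
        )
        return ModelParams(pi=0.0, mu=current.mu, sigma=current.sigma)
    mu = float((w @ m1) / sw)
    var = float((w @ (m2 - 2.0 * mu * m1 + mu**2)) / sw)
    sigma = max(np.sqrt(max(var, 0.0)), sigma_min)
    return ModelParams(pi=pi, mu=mu, sigma=float(sigma))


def _is_boundary(pi: float) -> bool:
    return pi <= BOUNDARY_TOL or pi >= 1.0 - BOUNDARY_TOL


def _fit_em_single(
    compiled: _CompiledDataset,
    init: ModelParams,
    grid_k: int,
    tol: float,
    param_tol: float,
    max_iter: int,
) -> FitResult:
    if compiled.p.size == 0:
        # flat likelihood: every case is empty. Any parameter value is a
        # maximizer; return the starting point unchanged for determinism.
        logger.warning(
            "dataset contains no mutations; likelihood is flat and the "
            "starting parameters are returned unchanged"
        )
        w = np.full(compiled.n, init.pi)
        posteriors = [
            CasePosterior(c.case_id, init.pi, init.mu, init.mu**2 + init.sigma**2)
            for c in compiled.cases
        ]
        return FitResult(
            params=init,
            loglik=0.0,
            method="em",
            converged=True,
            n_iter=0,
            boundary=_is_boundary(init.pi),
            loglik_trace=[0.0],
            posteriors=posteriors,
            message="flat likelihood (no mutations); initial parameters kept",
        )
    params = init
    loglik = None
    trace: list[float] = []
    converged = False
    message = ""
    n_iter = 0
    prev_params = init
    for n_iter in range(1, max_iter + 1):
        log_m, w, m1, m2 = _e_step_arrays(compiled, params, grid_k)
        new_loglik = _loglik_from_logm(compiled, params, log_m)
        if loglik is not None and new_loglik < loglik - 1e-10:
            # ascent stalled at the quadrature-error floor: the parameter
            # update no longer produces a resolvable likelihood gain. Keep
            # the previous (higher-likelihood) iterate.
            params = prev_params
            converged = True
            message = (
                "stopped: log-likelihood change fell below numerical "
                "resolution"
            )
            break
        trace.append(new_loglik)
        new_params = _m_step_arrays(w, m1, m2, params)
        delta_param = float(
            np.max(np.abs(new_params.as_array() - params.as_array()))
        )
        delta_ll = np.inf if loglik is None else abs(new_loglik - loglik)
        prev_params, params, loglik = params, new_params, new_loglik
        if delta_ll < tol and delta_param < param_tol:
            params = prev_params  # the parameters whose loglik was just taken
            converged = True
            break
    log_m, w, m1, m2 = _e_step_arrays(compiled, params, grid_k)
    loglik = _loglik_from_logm(compiled, params, log_m)
    if trace and loglik < trace[-1] - 1e-10:
        # the last M-step update failed to ascend (quadrature-error floor)
        params = prev_params
        log_m, w, m1, m2 = _e_step_arrays(compiled, params, grid_k)
        loglik = _loglik_from_logm(compiled, params, log_m)
    posteriors = [
        CasePosterior(case_id=c.case_id, w=float(wj), m1=float(a1), m2=float(a2))
        for c, wj, a1, a2 in zip(compiled.cases, w, m1, m2)
    ]
    if not converged:
        message = f"no convergence in {max_iter} iterations"
    return FitResult(
        params=params,
        loglik=loglik,
        method="em",
        converged=converged,
        n_iter=n_iter,
        boundary=_is_boundary(params.pi),
        loglik_trace=trace,
        posteriors=posteriors,
        message=message,
    )


def fit_em(
    dataset: Sequence[CasePair],
    init: ModelParams = DEFAULT_INIT,
    grid_k: int = 64,
    tol: float = 1e-6,
    param_tol: float = 1e-5,
    max_iter: int = 1000,
    multistart: bool = False,
) -> FitResult:
    """Fit by EM; optionally from several clonal-proportion starts.

    The observed-data log-likelihood is recomputed each iteration and is
    nondecreasing along the trajectory (up to quadrature round-off). With
    ``multistart`` the run with the best final log-likelihood wins.
    """
    compiled = _compile(dataset)
    starts = (
        [ModelParams(pi=p0, mu=init.mu, sigma=init.sigma) for p0 in MULTISTART_PI0]
        if multistart
        else [init]
    )
    results = [
        _fit_em_single(compiled, s, grid_k, tol, param_tol, max_iter)
        for s in starts
    ]
    return max(results, key=lambda r: r.loglik)


def _fit_onestep_single(
    compiled: _CompiledDataset, init: ModelParams, grid_k: int
) -> FitResult:
    def negloglik(theta: np.ndarray) -> float:
        pi, mu, sigma = theta
        params = ModelParams(pi=float(pi), mu=float(mu), sigma=float(sigma))
        return -compiled.marginal_loglik(params, build_grid(params, grid_k))

    res = minimize(
        negloglik,
        x0=init.as_array(),
        method="L-BFGS-B",
        bounds=_BOUNDS,
    )
    if not res.success:
        warnings.warn(
            f"one-step optimizer did not report success: {res.message}",
            RuntimeWarning,
            stacklevel=3,
        )
    params = ModelParams(
        pi=float(np.clip(res.x[0], 0.0, 1.0)),
        mu=float(res.x[1]),
        sigma=float(max(res.x[2], SIGMA_MIN)),
    )
    posteriors = e_step(compiled, params, grid_k)
    return FitResult(
        params=params,
        loglik=float(-res.fun),
        method="onestep",
        converged=bool(res.success),
        n_iter=int(res.nit),
        boundary=_is_boundary(params.pi),
        loglik_trace=[float(-res.fun)],
        posteriors=posteriors,
        message=str(res.message),
    )


def fit_onestep(
    dataset: Sequence[CasePair],
    init: ModelParams = DEFAULT_INIT,
    grid_k: int = 64,
    multistart: bool = False,
) -> FitResult:
    """Maximize the marginal likelihood directly under box constraints.

    L-BFGS-B over (pi, mu, sigma) with pi in [0, 1], mu in [-10, 10], sigma
    in [0.05, 10]. The boundary flag records a fitted clonal proportion on
    (or within 1e-8 of) 0 or 1.
    """
    compiled = _compile(dataset)
    starts = (
        [ModelParams(pi=p0, mu=init.mu, sigma=init.sigma) for p0 in MULTISTART_PI0]
        if multistart
        else [init]
    )
    results = [_fit_onestep_single(compiled, s, grid_k) for s in starts]
    return max(results, key=lambda r: r.loglik)


def posterior_clonality(
    dataset: Sequence[CasePair],
    params: ModelParams,
    grid_k: int = 64,
) -> np.ndarray:
    """Per-case posterior probabilities of clonality at the given parameters.

    The per-case diagnostic the model exists for: at a fitted clonal
    proportion of exactly 0 (or 1) every probability is forced to 0 (or 1),
    regardless of how rare a case's matches are.
    """
    return np.array([p.w for p in e_step(dataset, params, grid_k)])
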