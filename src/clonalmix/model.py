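"""Likelihood kernels for the clonal-relatedness random-effects model.

A case is a patient with two tumors. The observed data for case ``j`` are the
loci ``G_j`` mutated in at least one of the two tumors, each locus carrying a
known population occurrence probability ``p_i`` and a status: *shared* (the
identical mutation in both tumors, set ``A_j``) or *private* (mutated in
exactly one tumor, set ``B_j``).

The model places a latent clonality indicator ``C_j ~ Bernoulli(pi)`` on each
case. A clonal case carries a clonality signal ``xi_j`` in ``[0, 1)`` — the
anticipated fraction of its observed mutations that are matches — with
``-log(1 - xi_j)`` lognormal, i.e. ``u_j = log(-log(1 - xi_j))`` normal with
mean ``mu`` and standard deviation ``sigma``. Independent cases have
``xi_j = 0``.

Conditional on the signal, each observed locus is shared with probability

    clonal:      (xi + (1 - xi) p) / (xi + (1 - xi)(2 - p))
    independent:  p / (2 - p)

and private with the complementary probability. This module provides those
per-locus kernels, per-case log-likelihoods, the signal density, and a
Gauss-Hermite quadrature grid on the ``u`` scale used to marginalize the
signal out of the clonal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp, roots_hermite
from scipy.stats import norm

__all__ = [
    "SHARED",
    "PRIVATE",
    "MutationLocus",
    "CasePair",
    "ModelParams",
    "SignalValue",
    "QuadratureGrid",
    "SIGMA_MIN",
    "xi_from_u",
    "u_from_xi",
    "locus_prob_clonal",
    "locus_prob_independent",
    "case_loglik_clonal",
    "case_loglik_independent",
    "signal_logdensity",
    "build_grid",
    "case_marginal_loglik",
    "dataset_marginal_loglik",
]

SHARED = "shared"
PRIVATE = "private"

#: Lower bound kept on the signal scale parameter throughout fitting; a
#: degenerate point-mass signal breaks the quadrature and is never supported
#: by the handful of informative cases a real panel study contains.
SIGMA_MIN = 0.05


@dataclass(frozen=True)
class MutationLocus:
    """One locus observed mutated in a tumor pair.

    Parameters
    ----------
    locus_id : opaque label.
    p : population probability that this mutation occurs in a tumor of the
        cancer type under study, strictly inside (0, 1).
    status : ``"shared"`` (mutated in both tumors) or ``"private"``.
    """

    locus_id: str
    p: float
    status: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(
                f"locus {self.locus_id!r}: occurrence probability must lie "
                f"strictly in (0, 1), got {self.p!r}"
            )
        if self.status not in (SHARED, PRIVATE):
            raise ValueError(
                f"locus {self.locus_id!r}: status must be {SHARED!r} or "
                f"{PRIVATE!r}, got {self.status!r}"
            )

    @property
    def shared(self) -> bool:
        return self.status == SHARED


@dataclass(frozen=True)
class CasePair:
    """The informative data for one case: all loci mutated in either tumor.

    A case with no observed mutations is legal and contributes a factor of 1
    to every likelihood.
    """

    case_id: str
    loci: tuple[MutationLocus, ...] = ()

    def __init__(self, case_id: str, loci: Iterable[MutationLocus] = ()) -> None:
        object.__setattr__(self, "case_id", case_id)
        object.__setattr__(self, "loci", tuple(loci))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_shared(self) -> int:
        return sum(1 for l in self.loci if l.shared)

    @property
    def n_private(self) -> int:
        return self.n_loci - self.n_shared

    def p_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Occurrence probabilities split into (shared, private) arrays."""
        ps = np.array([l.p for l in self.loci if l.shared], dtype=float)
        pp = np.array([l.p for l in self.loci if not l.shared], dtype=float)
        return ps, pp


@dataclass(frozen=True)
class ModelParams:
    """Population parameters: clonal proportion and signal distribution.

    ``pi`` is the proportion of clonal cases in [0, 1]; ``mu`` and ``sigma``
    are the mean and standard deviation of ``u = log(-log(1 - xi))`` for
    clonal cases (equivalently, ``-log(1 - xi)`` is lognormal(mu, sigma)).
    """

    pi: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must be in [0, 1], got {self.pi!r}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi, self.mu, self.sigma], dtype=float)


@dataclass(frozen=True)
class SignalValue:
    """A clonality signal on both scales: ``xi`` in [0, 1) and ``u`` real.

    ``xi = 1 - exp(-exp(u))``. Simulation truth records carry the latent
    clonality indicator alongside; independent cases have ``xi = 0`` (``u``
    undefined, stored as ``-inf``).
    """

    xi: float
    u: float

    @classmethod
    def from_u(cls, u: float) -> "SignalValue":
        return cls(xi=float(xi_from_u(u)), u=float(u))


def xi_from_u(u):
    """Map the normal scale ``u`` to the signal scale: ``1 - exp(-e^u)``."""
    return -np.expm1(-np.exp(u))


def u_from_xi(xi):
    """Inverse of :func:`xi_from_u`; requires ``0 < xi < 1``."""
    return np.log(-np.log1p(-np.asarray(xi, dtype=float)))


def _check_xi(xi: float) -> None:
    if not (0.0 <= xi < 1.0):
        raise ValueError(f"clonality signal must lie in [0, 1), got {xi!r}")


def locus_prob_clonal(xi: float, locus: MutationLocus) -> float:
    """P(locus status | signal xi, clonal case).

    Shared loci have probability ``(xi + (1-xi)p) / (xi + (1-xi)(2-p))``;
    private loci the complementary ``2(1-xi)(1-p) / (xi + (1-xi)(2-p))``.
    At ``xi = 0`` this reduces exactly to the independent-case kernel.
    """
    _check_xi(xi)
    p = locus.p
    denom = 2.0 - p - xi * (1.0 - p)  # == xi + (1 - xi)(2 - p)
    if locus.shared:
        return (p + xi * (1.0 - p)) / denom
    return 2.0 * (1.0 - xi) * (1.0 - p) / denom


def locus_prob_independent(locus: MutationLocus) -> float:
    """P(locus status | independent case): ``p/(2-p)`` shared, rest private."""
    p = locus.p
    if locus.shared:
        return p / (2.0 - p)
    return 2.0 * (1.0 - p) / (2.0 - p)


def case_loglik_clonal(case: CasePair, xi: float) -> float:
    """Log P(Y_j | xi, C_j = 1): sum of per-locus log kernels over G_j.

    Zero for an empty case. ``-inf`` only in the limiting corner ``xi -> 1``
    with a private locus present.
    """
    _check_xi(xi)
    ps, pp = case.p_arrays()
    log1m_xi = np.log1p(-xi)
    out = 0.0
    if ps.size:
        out += float(np.sum(np.log(ps + xi * (1.0 - ps))))
        out -= float(np.sum(np.log(2.0 - ps - xi * (1.0 - ps))))
    if pp.size:
        with np.errstate(divide="ignore"):
            out += float(
                np.sum(np.log(2.0) + log1m_xi + np.log1p(-pp))
                - np.sum(np.log(2.0 - pp - xi * (1.0 - pp)))
            )
    return out


def case_loglik_independent(case: CasePair) -> float:
    """Log P(Y_j | C_j = 0); equals ``case_loglik_clonal(case, 0)``."""
    ps, pp = case.p_arrays()
    out = 0.0
    if ps.size:
        out += float(np.sum(np.log(ps) - np.log(2.0 - ps)))
    if pp.size:
        out += float(np.sum(np.log(2.0) + np.log1p(-pp) - np.log(2.0 - pp)))
    return out


def signal_logdensity(u, params: ModelParams):
    """Log-density of the transformed signal ``u = log(-log(1-xi))``.

    ``u`` is normal with mean ``params.mu`` and sd ``params.sigma``; on the
    ``-log(1-xi)`` scale the signal is lognormal(mu, sigma).
    """
    if params.sigma <= 0.0:
        raise ValueError("sigma must be positive")
    return norm.logpdf(u, loc=params.mu, scale=params.sigma)


@dataclass(frozen=True)
class QuadratureGrid:
    """Gauss-Hermite nodes/weights for expectations over the signal.

    Nodes live on the ``u`` scale, where the signal is exactly normal, so
    ``sum_k w_k f(xi(u_k))`` approximates ``E_g[f(xi)]`` for smooth ``f``.
    Weights are renormalized to sum to one.
    """

    nodes: np.ndarray
    weights: np.ndarray
    log_weights: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return self.nodes.size

    @property
    def xi(self) -> np.ndarray:
        return xi_from_u(self.nodes)


@lru_cache(maxsize=8)
def _hermite_rule(k: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = roots_hermite(k)
    h.setflags(write=False)
    w.setflags(write=False)
    return h, w


def build_grid(params: ModelParams, k: int = 64) -> QuadratureGrid:
    """Quadrature grid adapted to the signal distribution of ``params``."""
    if k < 2:
        raise ValueError("need at least 2 quadrature nodes")
    h, w = _hermite_rule(k)
    nodes = params.mu + np.sqrt(2.0) * params.sigma * h
    weights = w / np.sqrt(np.pi)
    weights = weights / weights.sum()
    return QuadratureGrid(
        nodes=nodes, weights=weights, log_weights=np.log(weights)
    )


def _clonal_loglik_nodes(case: CasePair, grid: QuadratureGrid) -> np.ndarray:
    """Vector of log P(Y_j | xi(u_k), C=1) over the grid nodes."""
    ps, pp = case.p_arrays()
    u = grid.nodes
    xi = xi_from_u(u)[:, None]
    out = np.zeros(grid.k)
    if ps.size:
        out += np.sum(np.log(ps + xi * (1.0 - ps)), axis=1)
        out -= np.sum(np.log(2.0 - ps - xi * (1.0 - ps)), axis=1)
    if pp.size:
        # log(1 - xi) = -e^u exactly: no cancellation when xi rounds to 1
        log1m_xi = -np.exp(u)[:, None]
        out += np.sum(np.log(2.0) + log1m_xi + np.log1p(-pp), axis=1)
        out -= np.sum(np.log(2.0 - pp - xi * (1.0 - pp)), axis=1)
    return out


def case_clonal_marginal_loglik(case: CasePair, grid: QuadratureGrid) -> float:
    """Log of the clonal likelihood integrated over the signal distribution."""
    return float(logsumexp(grid.log_weights + _clonal_loglik_nodes(case, grid)))


def case_marginal_loglik(
    case: CasePair, params: ModelParams, grid: QuadratureGrid
) -> float:
    """Log of one case's mixture likelihood contribution.

    ``log[ pi * int P(Y|xi,C=1) g(xi) dxi + (1-pi) * P(Y|C=0) ]``, computed
    with log-sum-exp throughout so cases with up to hundreds of loci and
    occurrence probabilities down to 1e-6 neither overflow nor underflow.
    """
    log_indep = case_loglik_independent(case)
    if params.pi == 0.0:
        return log_indep
    log_clonal = case_clonal_marginal_loglik(case, grid)
    if params.pi == 1.0:
        return log_clonal
    return float(
        np.logaddexp(
            np.log(params.pi) + log_clonal,
            np.log1p(-params.pi) + log_indep,
        )
    )


def dataset_marginal_loglik(
    cases: Sequence[CasePair], params: ModelParams, k: int = 64
) -> float:
    """Observed-data log-likelihood of the whole sample."""
    grid = build_grid(params, k)
    return float(sum(case_marginal_loglik(c, params, grid) for c in cases))
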