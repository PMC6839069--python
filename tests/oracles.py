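"""Independent reference computations used by the test suite.

Everything here deliberately avoids the package's quadrature/EM code paths:
adaptive integration via scipy.integrate.quad, brute-force optimization via
scipy.optimize, and closed forms evaluated directly.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.stats import norm

from clonalmix import (
    CasePair,
    ModelParams,
    case_loglik_clonal,
    case_loglik_independent,
    xi_from_u,
)


def adaptive_clonal_marginal(case: CasePair, params: ModelParams) -> float:
    """int P(Y | xi(u), C=1) N(u; mu, sigma) du by adaptive quadrature."""
    lo = params.mu - 12.0 * params.sigma
    hi = params.mu + 12.0 * params.sigma
    xi_max = np.nextafter(1.0, 0.0)  # far tail rounds to xi == 1 in floats

    def integrand(u: float) -> float:
        xi = min(float(xi_from_u(u)), xi_max)
        return np.exp(case_loglik_clonal(case, xi)) * norm.pdf(
            u, params.mu, params.sigma
        )

    val, _ = quad(integrand, lo, hi, limit=300)
    return float(val)


def adaptive_marginal_loglik(case: CasePair, params: ModelParams) -> float:
    """Mixture likelihood contribution of one case, no fixed grid."""
    indep = np.exp(case_loglik_independent(case))
    if params.pi == 0.0:
        return float(np.log(indep))
    m = adaptive_clonal_marginal(case, params)
    return float(np.log(params.pi * m + (1.0 - params.pi) * indep))


def adaptive_posterior_w(case: CasePair, params: ModelParams) -> float:
    """Bayes posterior P(C=1 | Y) via adaptive integration."""
    m = adaptive_clonal_marginal(case, params)
    indep = np.exp(case_loglik_independent(case))
    a = params.pi * m
    return float(a / (a + (1.0 - params.pi) * indep))


def expected_complete_loglik(theta, w, m1, m2) -> float:
    """Expected complete-data log-likelihood surface (additive constants in
    the data terms dropped; they do not depend on the parameters)."""
    pi, mu, sigma = theta
    gauss = (
        -np.log(sigma)
        - 0.5 * np.log(2.0 * np.pi)
        - (m2 - 2.0 * mu * m1 + mu**2) / (2.0 * sigma**2)
    )
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi) if pi > 0 else -np.inf
        log_1mpi = np.log1p(-pi) if pi < 1 else -np.inf
    per_case = w * (log_pi + gauss) + (1.0 - w) * log_1mpi
    return float(per_case.sum())


def brute_force_m_step(w, m1, m2) -> np.ndarray:
    """Numerically maximize the expected complete-data log-likelihood."""
    best = None
    for x0 in ([0.5, 0.0, 1.0], [0.2, -1.0, 0.5], [0.8, 1.0, 2.0]):
        res = minimize(
            lambda th: -expected_complete_loglik(th, w, m1, m2),
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=((1e-9, 1 - 1e-9), (-10, 10), (0.05, 10)),
            options={"ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def random_case(rng: np.random.Generator, max_loci: int = 10) -> CasePair:
    """A random tumor-pair case with mixed rare/common loci."""
    from clonalmix import PRIVATE, SHARED, MutationLocus

    n = int(rng.integers(0, max_loci + 1))
    loci = []
    for i in range(n):
        p = float(10 ** rng.uniform(-5, np.log10(0.3)))
        status = SHARED if rng.random() < 0.3 else PRIVATE
        loci.append(MutationLocus(f"l{i}", p, status))
    return CasePair("rand", loci)


def random_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        pi=float(rng.uniform(0.02, 0.98)),
        mu=float(rng.uniform(-3.0, 1.5)),
        sigma=float(rng.uniform(0.1, 1.5)),
    )
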