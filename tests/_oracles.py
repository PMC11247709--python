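"""Independent numerical oracles used only by the test suite.

These deliberately avoid the code paths they check: transition probabilities
via the uniformization series rather than scaling-and-squaring, and the
any-domain-impaired probability via one-dimensional quadrature over the
shared factor rather than simulation.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def uniformization_probability(Q: np.ndarray, t: float, tol: float = 1e-14) -> np.ndarray:
    """P(t) = sum_k Pois(k; qt) M^k with M = I + Q/q, q >= max_i |Q_ii|.

    The series is truncated when the remaining Poisson tail falls below
    ``tol``; for a valid generator this matches expm(Qt) to high accuracy.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    q = max(np.max(-np.diag(Q)), 1e-12)
    M = np.eye(n) + Q / q
    mu = q * t
    P = np.zeros((n, n))
    Mk = np.eye(n)
    log_w = -mu  # log Poisson weight at k = 0
    acc = 0.0
    k = 0
    while acc < 1 - tol:
        w = np.exp(log_w)
        P += w * Mk
        acc += w
        k += 1
        log_w += np.log(mu) - np.log(k) if mu > 0 else -np.inf
        Mk = Mk @ M
        if k > 10000:  # pragma: no cover - safety
            break
    return P


def any_domain_below(threshold: float, rho: float, n_domains: int = 5) -> float:
    """P(min of equicorrelated standard normals <= -threshold).

    For exchangeable correlation rho >= 0 the variables share one factor:
    Z_i = sqrt(rho) U + sqrt(1-rho) e_i, so the probability is a single
    integral over U.
    """
    if rho == 0:
        return 1.0 - stats.norm.cdf(threshold) ** n_domains
    a = np.sqrt(rho)
    b = np.sqrt(1 - rho)

    def integrand(u):
        return stats.norm.pdf(u) * stats.norm.cdf((threshold + a * u) / b) ** n_domains

    val, _ = integrate.quad(integrand, -12, 12, limit=200)
    return 1.0 - val
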