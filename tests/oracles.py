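"""Independent numerical oracles used by the test suite only.

The conjugate posterior mean is checked against a direct numerical
integration of (multinomial likelihood x Dirichlet prior) over the
probability simplex.  The integrand carries boundary singularities
theta_j**(a_j - 1) with a_j < 1, so plain grid rules converge far too
slowly; instead the simplex is mapped to a unit cube by stick-breaking
(theta_1 = x_1, theta_i = x_i * prod_{k<i}(1 - x_k)) and each axis is
integrated with Gauss-Jacobi rules whose weight absorbs the singular
kernel exactly.  The smooth remainder of the integrand is evaluated at
the quadrature nodes, so the conjugate closed form is never used.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import roots_jacobi


def _axis_rules(exponents_p, exponents_q, n_nodes):
    """Per-axis nodes on (0,1) and weights for x^(p-1) (1-x)^(q-1)."""
    rules = []
    for p, q in zip(exponents_p, exponents_q):
        nodes, weights = roots_jacobi(n_nodes, q - 1.0, p - 1.0)
        x = (nodes + 1.0) / 2.0
        w = weights / 2.0 ** (p + q - 1.0)
        rules.append((x, w))
    return rules


def simplex_moment(exponents, smooth=None, n_nodes=24):
    """integral over the simplex of smooth(theta) * prod theta_i**(e_i - 1).

    ``smooth`` maps a theta vector to a float (default 1).  Exact for
    polynomial ``smooth`` of degree < 2*n_nodes.
    """
    e = np.asarray(exponents, dtype=float)
    m = e.size
    if m == 1:
        return smooth(np.array([1.0])) if smooth else 1.0
    # stick-breaking: axis i has kernel x^(e_i - 1) (1-x)^(tail_i - 1)
    tails = np.array([e[i + 1:].sum() for i in range(m - 1)])
    rules = _axis_rules(e[: m - 1], tails, n_nodes)
    total = 0.0
    for combo in product(*(range(n_nodes) for _ in range(m - 1))):
        weight = 1.0
        theta = np.empty(m)
        remaining = 1.0
        for axis, idx in enumerate(combo):
            x, w = rules[axis]
            weight *= w[idx]
            theta[axis] = x[idx] * remaining
            remaining *= 1.0 - x[idx]
        theta[m - 1] = remaining
        total += weight * (smooth(theta) if smooth else 1.0)
    return total


def posterior_mean_by_integration(alpha_prior, counts, n_nodes=24):
    """E(theta | counts) from brute-force integration on the simplex.

    Numerator and denominator are both integrals of the unnormalized
    posterior kernel prod theta_i**(alpha_i + I_i - 1); the numerator
    carries the smooth extra factor theta_j evaluated at the nodes.
    """
    alpha = np.asarray(alpha_prior, dtype=float)
    counts = np.asarray(counts, dtype=float)
    exponents = alpha + counts
    den = simplex_moment(exponents, None, n_nodes)
    means = np.empty(alpha.size)
    for j in range(alpha.size):
        num = simplex_moment(exponents, lambda t, j=j: t[j], n_nodes)
        means[j] = num / den
    return means


def posterior_mean_beta_quad(alpha_prior, counts):
    """m = 2 cross-check via adaptive scipy quadrature (quadpack)."""
    from scipy.integrate import quad

    a = np.asarray(alpha_prior, float) + np.asarray(counts, float)
    if a.size != 2:
        raise ValueError("adaptive cross-check is 1-dimensional (m = 2)")

    def kernel(t):
        return t ** (a[0] - 1.0) * (1.0 - t) ** (a[1] - 1.0)

    opts = dict(points=[0.0, 1.0], limit=400, epsabs=1e-13, epsrel=1e-12)
    den, _ = quad(kernel, 0.0, 1.0, **opts)
    num, _ = quad(lambda t: t * kernel(t), 0.0, 1.0, **opts)
    return np.array([num / den, 1.0 - num / den])


def temporal_bin_by_enumeration(offset_days, window_days, max_bins=100):
    """Which half-open backward window [b*T, (b-1)*T) holds the offset.

    Windows are enumerated directly from their interval definition:
    bin b covers offsets d with (b-1)*T < d <= b*T.
    """
    for b in range(1, max_bins + 1):
        if (b - 1) * window_days < offset_days <= b * window_days:
            return b
    raise AssertionError("offset beyond enumerated windows")
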