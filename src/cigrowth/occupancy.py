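"""Neighborhood-occupancy probability models.

The central quantity is the expected probability E[ℙ(ω|n)] that a focal
cell's entire birth neighborhood (ω sites) is occupied when n of the l
lattice sites hold cells — the blocked-birth probability that converts
the microscopic contact-inhibition rule into macroscopic growth laws.

Regimes
-------
well-mixed exact
    Cells placed uniformly at random (fast migration): the number of
    occupied neighbor sites is hypergeometric, ℙ(x|n) =
    C(ω,x)·C(l−ω−1, n−1−x) / C(l−1, n−1); blocked = ℙ(ω|n).
well-mixed approximate
    (n/l)^ω, the l, n ≫ ω limit of the above (variant ((n−1)/(l−1))^ω
    available).
radial
    A compact cluster with no migration: only surface cells can divide,
    blocked = interior fraction = (1 − n^(−1/d))^d, first order
    1 − d·n^(−1/d).
fractal
    Same first-order form; the fractal dimension enters the growth law,
    not the blocked probability.
indicator
    ω = l−1 (a daughter can go anywhere): blocked = 𝟙[n ≥ l].

Binomial coefficients are evaluated in log space (gammaln) so lattices
up to ~10⁶ sites pose no overflow problem.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "neighbor_pmf",
    "blocked_prob_exact",
    "blocked_prob_wellmixed",
    "blocked_prob_radial",
    "blocked_prob_indicator",
]


def _log_comb(a, b):
    """log C(a, b) with the convention C(a,b)=0 outside 0 ≤ b ≤ a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


def neighbor_pmf(x, n, l, omega):
    """ℙ(X = x | n): probability of exactly x occupied neighbor sites.

    Hypergeometric placement of the n−1 non-focal cells among the l−1
    non-focal sites, of which ω form the neighborhood.  Vectorized over
    ``x`` and ``n``.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    if np.any(omega >= l):
        raise ValueError("neighborhood size must be below l (only l-1 other sites)")
    if np.any((n < 1) | (n > l)):
        raise ValueError("n must lie in 1..l")
    if np.any((x < 0) | (x > omega)):
        raise ValueError("x must lie in 0..omega")
    logp = (
        _log_comb(omega, x)
        + _log_comb(l - omega - 1, n - 1 - x)
        - _log_comb(l - 1, n - 1)
    )
    out = np.exp(logp)
    return out if out.ndim else float(out)


def blocked_prob_exact(n, l, omega):
    """E[ℙ(ω|n)] in the well-mixed regime: neighbor_pmf at x = ω.

    Zero whenever n−1 < ω, one at n = l, non-decreasing in n.
    """
    return neighbor_pmf(omega, n, l, omega)


def blocked_prob_wellmixed(n, l, omega, *, shifted=False):
    """Mean-field approximation (n/l)^ω.

    ``shifted=True`` uses ((n−1)/(l−1))^ω, the intermediate form before
    the final n, l ≫ 1 simplification.
    """
    n = np.asarray(n, dtype=float)
    if shifted:
        out = ((n - 1) / (l - 1)) ** omega
    else:
        out = (n / l) ** omega
    return out if out.ndim else float(out)


def blocked_prob_radial(n, d=2, order="exact"):
    """Blocked probability of a compact radially growing cluster.

    ``exact``: (1 − n^(−1/d))^d (interior fraction of a d-cube of n
    cells); ``first_order``: 1 − d·n^(−1/d), clamped to [0, 1] since the
    Taylor form goes negative at small n where it is invalid anyway.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if d not in (2, 3):
        raise ValueError("embedding dimension d must be 2 or 3")
    if order == "exact":
        out = (1.0 - n ** (-1.0 / d)) ** d
    elif order == "first_order":
        out = np.clip(1.0 - d * n ** (-1.0 / d), 0.0, 1.0)
    else:
        raise ValueError(f"unknown order: {order!r}")
    return out if out.ndim else float(out)


def blocked_prob_indicator(n, l):
    """ω = l−1 regime: 0 below saturation, 1 at n ≥ l (exponential law)."""
    n = np.asarray(n)
    out = (n >= l).astype(float)
    return out if out.ndim else float(out)
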