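"""Mean-field growth laws arising from contact-inhibited birth.

Each law is the single equation u̇ = λu(1 − E[ℙ(ω|n)]) − δu with a
different closed form for the blocked-birth probability E[ℙ(ω|n)]:

=================  ====================================================
exponential        u̇ = (λ − δ)u                     (never blocked)
radial             ṅ = λ d n^((d−1)/d) − δn         (surface growth;
                   d = 3 gives the Von Bertalanffy model)
fractal            ṅ = λ a n^(D/d) − δn             (d−1 < D ≤ d)
gen_logistic       u̇ = λu(1 − u^ω̄) − δu            (Richards equation)
gen_logistic_2nd   u̇ = λu(1 − u^ω̄(1 + ½σ_ω²(ln u)²)) − δu
gompertz           u̇ = −λω̄ u ln u − δu
gompertz_2nd       u̇ = −λu(ω̄ ln u + ½(σ_ω² + ω̄²)(ln u)²) − δu
exp_indicator      u̇ = λu(1 − 𝟙[u ≥ 1]) − δu       (exponential until
                   saturation; ω = l−1)
=================  ====================================================

Density laws use the confluence u = n/l ∈ [0, 1]; the radial and
fractal laws are integrated in cell count n (canonical form), with the
density version a plain n/l rescaling.

The validity conditions of the two Taylor-expansion laws are exposed as
:func:`gompertz_condition` (2ω̄/(σ_ω²+ω̄²) ≫ |ln u|) and
:func:`genlogistic_condition` (2 ≫ σ_ω²(ln u)²), with "≫" read as a
configurable margin ratio (default 10×).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GrowthLawSpec",
    "rhs",
    "solve",
    "genlogistic_solution",
    "gompertz_solution",
    "gompertz_condition",
    "genlogistic_condition",
    "LAWS",
]

LAWS = (
    "exponential", "radial", "fractal", "gen_logistic", "gen_logistic_2nd",
    "gompertz", "gompertz_2nd", "exp_indicator",
)

_EPS = 1e-30  # guards divisions by |ln u| at u = 1


@dataclass(frozen=True)
class GrowthLawSpec:
    """One growth law with its parameters.

    λ (``lam``) and δ (``delta``) are per-unit-time birth and death
    rates; ω̄ (``omega_bar``) the mean birth-neighborhood size and σ_ω
    (``sigma_omega``) its standard deviation; ``d`` the embedding
    dimension, ``D`` the fractal dimension and ``a`` the fractal
    prefactor (cell length-scale constant).
    """

    law: str
    lam: float = 0.1
    delta: float = 0.0
    omega_bar: float = 8.0
    sigma_omega: float = 0.0
    d: int = 2
    D: float = 1.0
    a: float = 2.0

    def __post_init__(self):
        if self.law not in LAWS:
            raise ValueError(f"unknown growth law: {self.law!r}")
        if self.lam < 0 or self.delta < 0:
            raise ValueError("rates must be nonnegative")
        if not np.isfinite([self.lam, self.delta, self.omega_bar,
                            self.sigma_omega, self.D, self.a]).all():
            raise ValueError("non-finite parameter")
        if self.law in ("gen_logistic", "gen_logistic_2nd", "gompertz",
                        "gompertz_2nd") and self.omega_bar <= 0:
            raise ValueError("omega_bar must be positive")
        if self.law in ("radial", "fractal") and self.d not in (2, 3):
            raise ValueError("d must be 2 or 3")
        if self.law == "fractal" and not (self.d - 1 < self.D <= self.d):
            raise ValueError("fractal dimension must satisfy d-1 < D <= d")
        if self.law == "fractal" and self.a <= 0:
            raise ValueError("fractal prefactor a must be positive")

    @property
    def count_based(self) -> bool:
        return self.law in ("radial", "fractal")


def rhs(spec: GrowthLawSpec, state):
    """Time derivative of the state (u for density laws, n for
    radial/fractal)."""
    s = np.asarray(state, dtype=float)
    lam, delta = spec.lam, spec.delta
    law = spec.law
    if law in ("gompertz", "gompertz_2nd") and np.any(s <= 0):
        raise ValueError("gompertz-family rhs requires u > 0 (ln u defined)")
    if law == "exponential":
        out = lam * s - delta * s
    elif law == "radial":
        out = lam * spec.d * s ** ((spec.d - 1) / spec.d) - delta * s
    elif law == "fractal":
        out = lam * spec.a * s ** (spec.D / spec.d) - delta * s
    elif law == "gen_logistic":
        out = lam * s * (1.0 - s ** spec.omega_bar) - delta * s
    elif law == "gen_logistic_2nd":
        with np.errstate(divide="ignore", invalid="ignore"):
            ln = np.where(s > 0, np.log(np.maximum(s, _EPS)), 0.0)
        out = lam * s * (1.0 - s ** spec.omega_bar
                         * (1.0 + 0.5 * spec.sigma_omega ** 2 * ln ** 2)) - delta * s
    elif law == "gompertz":
        out = -lam * spec.omega_bar * s * np.log(s) - delta * s
    elif law == "gompertz_2nd":
        ln = np.log(s)
        out = -lam * s * (spec.omega_bar * ln
                          + 0.5 * (spec.sigma_omega ** 2 + spec.omega_bar ** 2) * ln ** 2) \
            - delta * s
    elif law == "exp_indicator":
        out = lam * s * (1.0 - (s >= 1.0)) - delta * s
    return out if out.ndim else float(out)


def genlogistic_solution(t, u0, lam, omega, delta=0.0):
    """Closed-form trajectory of u̇ = λu(1 − u^ω) − δu.

    The substitution v = u^(−ω) linearizes the Bernoulli equation:
    v(t) = λ/(λ−δ) + (u0^(−ω) − λ/(λ−δ))·e^(−ω(λ−δ)t) for λ ≠ δ, and
    v(t) = u0^(−ω) + λωt at λ = δ.
    """
    t = np.asarray(t, dtype=float)
    if u0 <= 0:
        raise ValueError("u0 must be positive")
    r = lam - delta
    if abs(r) < 1e-14:
        v = u0 ** (-omega) + lam * omega * t
    else:
        vstar = lam / r
        v = vstar + (u0 ** (-omega) - vstar) * np.exp(-omega * r * t)
    with np.errstate(invalid="ignore"):
        u = np.where(v > 0, v ** (-1.0 / omega), np.inf)
    return u if u.ndim else float(u)


def gompertz_solution(t, u0, lam, omega, delta=0.0):
    """Closed-form trajectory of u̇ = −λω u ln u − δu.

    With w = ln u: ẇ = −λω w − δ, so
    w(t) = (ln u0 + δ/(λω))·e^(−λωt) − δ/(λω).
    """
    t = np.asarray(t, dtype=float)
    if u0 <= 0:
        raise ValueError("u0 must be positive")
    k = lam * omega
    if k < 1e-300:
        w = np.log(u0) - delta * t
    else:
        c = delta / k
        w = (np.log(u0) + c) * np.exp(-k * t) - c
    u = np.exp(w)
    return u if u.ndim else float(u)


def solve(spec: GrowthLawSpec, y0: float, t):
    """Integrate the law on the time grid ``t`` from initial density u0
    (or count n0 for radial/fractal).

    Uses an adaptive stiff-capable integrator (LSODA) at tight
    tolerances; the exp_indicator law is handled analytically so growth
    halts exactly at u = 1.
    """
    t = np.asarray(t, dtype=float)
    if y0 < 0 or not np.isfinite(y0):
        raise ValueError("initial condition must be finite and nonnegative")
    if spec.law in ("gompertz", "gompertz_2nd") and y0 <= 0:
        raise ValueError("gompertz-family initial density must be positive")
    if spec.law == "exp_indicator":
        r = spec.lam - spec.delta
        u = y0 * np.exp(r * (t - t[0]))
        if r > 0:
            u = np.minimum(u, 1.0)  # saturation is absorbing when λ > δ
        return u
    sol = solve_ivp(
        lambda _t, y: np.atleast_1d(rhs(spec, np.maximum(y, _EPS)
                                        if spec.law.startswith("gompertz") else y)),
        (t[0], t[-1]), [y0], t_eval=t, method="LSODA",
        rtol=1e-10, atol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.y[0]


def gompertz_condition(omega_bar, sigma_omega, u, threshold=10.0):
    """Validity check for dropping the (ln u)² term of the small-ω
    expansion: 2ω̄/(σ_ω² + ω̄²) ≫ |ln u|.

    Returns ``(holds, margin)`` where margin is the ratio of the two
    sides; ``holds`` when margin ≥ threshold.
    """
    if omega_bar <= 0:
        raise ValueError("omega_bar must be positive")
    if np.any(np.asarray(u) <= 0):
        raise ValueError("u must be positive")
    lhs = 2.0 * omega_bar / (sigma_omega ** 2 + omega_bar ** 2)
    margin = lhs / max(abs(float(np.log(u))), _EPS)
    return margin >= threshold, margin


def genlogistic_condition(sigma_omega, u, threshold=10.0):
    """Validity check for approximating the birth neighborhood by its
    mean: 2 ≫ σ_ω²(ln u)²; returns ``(holds, margin)``."""
    if np.any(np.asarray(u) <= 0):
        raise ValueError("u must be positive")
    margin = 2.0 / max(sigma_omega ** 2 * float(np.log(u)) ** 2, _EPS)
    return margin >= threshold, margin
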