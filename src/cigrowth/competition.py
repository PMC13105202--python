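"""Two-subpopulation competition under contact-inhibited growth laws.

An ad hoc superposition of two density-law populations that compete for
the same space: the contact-inhibition term of each subpopulation is
evaluated at the *total* density U = u₁ + u₂, so

    generalized logistic:  u̇ᵢ = λᵢ uᵢ (1 − U^ωᵢ) − δᵢ uᵢ
    Gompertz:              u̇ᵢ = −λᵢ ωᵢ uᵢ ln U − δᵢ uᵢ

Total-density coupling keeps overall confluence on a consistent
monotone growth curve while the subpopulations compete, and reduces
exactly to the single-population law when one density is zero.  A
subpopulation with a lower birth rate can still invade if its birth
neighborhood ω is large enough — the invasion-boundary scan maps that
trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CompetitionSpec",
    "competition_rhs",
    "simulate_competition",
    "classify_outcome",
    "invasion_boundary",
]

_EPS = 1e-30


@dataclass(frozen=True)
class CompetitionSpec:
    """Parameters of two competing subpopulations."""

    law: str  # "gen_logistic" | "gompertz"
    lam1: float
    omega1: float
    lam2: float
    omega2: float
    delta1: float = 0.0
    delta2: float = 0.0
    u1_0: float = 0.01
    u2_0: float = 0.01
    t_max: float = 2000.0
    rtol: float = 1e-9
    atol: float = 1e-12
    u_ext: float = 1e-6  # extinction threshold
    eq_rtol: float = 1e-8  # steady-state detection

    def __post_init__(self):
        if self.law not in ("gen_logistic", "gompertz"):
            raise ValueError(f"unknown competition law: {self.law!r}")
        if min(self.lam1, self.lam2, self.delta1, self.delta2) < 0:
            raise ValueError("rates must be nonnegative")
        if self.omega1 <= 0 or self.omega2 <= 0:
            raise ValueError("birth neighborhoods must be positive")
        if self.u1_0 < 0 or self.u2_0 < 0:
            raise ValueError("initial densities must be nonnegative")
        if self.u1_0 + self.u2_0 > 1.0 + 1e-12:
            raise ValueError("initial densities must sum to at most 1")


def competition_rhs(spec: CompetitionSpec, u1: float, u2: float):
    """(du₁/dt, du₂/dt) at the given densities."""
    U = u1 + u2
    if spec.law == "gompertz":
        if U <= 0:
            raise ValueError("gompertz coupling requires positive total density")
        lnU = np.log(U)
        d1 = -spec.lam1 * spec.omega1 * u1 * lnU - spec.delta1 * u1
        d2 = -spec.lam2 * spec.omega2 * u2 * lnU - spec.delta2 * u2
    else:
        inh1 = 1.0 - U ** spec.omega1
        inh2 = 1.0 - U ** spec.omega2
        d1 = spec.lam1 * u1 * inh1 - spec.delta1 * u1
        d2 = spec.lam2 * u2 * inh2 - spec.delta2 * u2
    return float(d1), float(d2)


def _rhs_vec(spec):
    def f(_t, y):
        u1 = max(y[0], 0.0)
        u2 = max(y[1], 0.0)
        if spec.law == "gompertz":
            U = max(u1 + u2, _EPS)
            lnU = np.log(U)
            return [-spec.lam1 * spec.omega1 * u1 * lnU - spec.delta1 * u1,
                    -spec.lam2 * spec.omega2 * u2 * lnU - spec.delta2 * u2]
        U = u1 + u2
        return [spec.lam1 * u1 * (1.0 - U ** spec.omega1) - spec.delta1 * u1,
                spec.lam2 * u2 * (1.0 - U ** spec.omega2) - spec.delta2 * u2]
    return f


def simulate_competition(spec: CompetitionSpec, t=None):
    """Integrate the pair of laws; returns (t, u1, u2, total)."""
    if t is None:
        t = np.linspace(0.0, spec.t_max, 501)
    t = np.asarray(t, dtype=float)
    sol = solve_ivp(_rhs_vec(spec), (t[0], t[-1]), [spec.u1_0, spec.u2_0],
                    t_eval=t, method="LSODA", rtol=spec.rtol, atol=spec.atol)
    if not sol.success:
        raise RuntimeError(f"competition integration failed: {sol.message}")
    # the true solutions are nonnegative; clip solver noise at the
    # absolute-tolerance floor
    u1 = np.maximum(sol.y[0], 0.0)
    u2 = np.maximum(sol.y[1], 0.0)
    return t, u1, u2, u1 + u2


def classify_outcome(spec: CompetitionSpec):
    """Long-run outcome for subpopulation 2.

    Returns a dict with ``outcome`` ∈ {"extinction_of_2",
    "takeover_by_2", "coexistence"}, final densities and a
    ``converged`` flag (False if densities still drift by more than
    ``eq_rtol`` relative over the final 10% of the horizon).
    """
    t, u1, u2, _ = simulate_competition(spec)
    tail = t >= t[0] + 0.9 * (t[-1] - t[0])
    drift = 0.0
    for u in (u1, u2):
        seg = u[tail]
        scale = max(abs(seg).max(), spec.u_ext)
        drift = max(drift, float(np.ptp(seg)) / scale)
    converged = drift < spec.eq_rtol  # relative drift over the final 10%
    u1f, u2f = float(u1[-1]), float(u2[-1])
    if u2f < spec.u_ext:
        outcome = "extinction_of_2"
    elif u1f < spec.u_ext:
        outcome = "takeover_by_2"
    else:
        outcome = "coexistence"
    return {"outcome": outcome, "u1_final": u1f, "u2_final": u2f,
            "converged": bool(converged)}


def invasion_boundary(base: CompetitionSpec, lam2_grid, omega2_grid):
    """Classify the outcome over a (λ₂, ω₂) grid.

    Returns a list of dict rows (lam2, omega2, outcome, u1_final,
    u2_final, converged).  With common death rates the outcome is
    monotone in λ₂ within each ω₂ column, so each column has a single
    invasion threshold.
    """
    rows = []
    for omega2 in omega2_grid:
        for lam2 in lam2_grid:
            spec = CompetitionSpec(**{**base.__dict__, "lam2": float(lam2),
                                      "omega2": float(omega2)})
            res = classify_outcome(spec)
            rows.append({"lam2": float(lam2), "omega2": float(omega2), **res})
    return rows
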