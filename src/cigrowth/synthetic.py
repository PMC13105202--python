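"""Synthetic confluency datasets for exercising the fitting pipeline.

Two generators:

* :func:`make_invitro_like` — emulates time-lapse confluency experiments
  on a panel of cell lines seeded at varied initial confluence.  Each
  line gets a birth-neighborhood size ω (log-uniform over a plausible
  range) and a birth rate tied to it by the inverse law λω = C, mimicking
  the anticorrelation observed across real lines; curves are the chosen
  law's trajectories with multiplicative log-normal measurement noise.
* :func:`make_abm_dataset` — runs the lattice ABM in the well-mixed
  regime (global migration, m·Δt = 1) over grids of initial confluence
  and birth neighborhood, the in silico analogue fitted in the same way.

Defaults: 7 lines on the C = 0.1 hyperbola, 50 time points spanning
growth from u₀ to ≈95% saturation, 2% multiplicative noise.  Both
generators are exactly reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .abm import SimParams, simulate
from .growth_laws import genlogistic_solution, gompertz_solution
from .lattice import init_state
from .neighborhoods import make_neighborhood

__all__ = ["SyntheticDataset", "make_invitro_like", "make_abm_dataset"]

#: named-preset birth neighborhoods available to the ABM generator
_PRESETS = {4: ("von_neumann", 1), 8: ("moore", 1), 12: ("von_neumann", 2),
            24: ("moore", 2)}


@dataclass
class SyntheticDataset:
    """A bundle of confluency series plus their generating parameters.

    Each row of ``series`` is a dict with keys ``line_id``,
    ``initial_confluence``, ``times``, ``densities``, ``law``, ``lam``,
    ``omega``, ``delta``, ``noise_sd``, ``seed``.
    """

    series: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.series)


def _solution(law, t, u0, lam, omega, delta):
    if law == "gen_logistic":
        return genlogistic_solution(t, u0, lam, omega, delta)
    if law == "gompertz":
        return gompertz_solution(t, u0, lam, omega, delta)
    raise ValueError(f"unknown law: {law!r}")


def _time_to_saturation(law, u0, lam, omega, delta, target=0.95):
    """Time at which the noiseless curve reaches ``target`` (or 98% of
    its equilibrium if that is lower)."""
    if law == "gen_logistic":
        ustar = (1.0 - delta / lam) ** (1.0 / omega) if delta < lam else 0.0
    else:
        ustar = np.exp(-delta / (lam * omega))
    goal = min(target, 0.98 * ustar) if ustar > u0 else None
    if goal is None or goal <= u0:
        return 10.0 / max(lam * min(omega, 1.0), 1e-6)  # decaying/flat: a few e-folds
    f = lambda t: _solution(law, t, u0, lam, omega, delta) - goal
    hi = 1.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 2.0
    return brentq(f, 0.0, hi)


def make_invitro_like(
    n_lines: int = 7,
    confluence_grid=(0.01, 0.05, 0.1, 0.3, 0.5),
    noise_sd: float = 0.02,
    law: str = "gen_logistic",
    C: float = 0.1,
    delta: float = 0.0,
    omega_range=(0.5, 24.0),
    n_points: int = 50,
    noise_model: str = "lognormal",
    seed: int = 0,
) -> SyntheticDataset:
    """Panel of noisy growth curves with λ and ω tied by λω = C."""
    if n_lines < 1 or len(confluence_grid) == 0:
        raise ValueError("need at least one line and one confluence value")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if any(not (0.0 < u < 1.0) for u in confluence_grid):
        raise ValueError("initial confluences must lie in (0, 1)")
    if noise_model not in ("lognormal", "additive"):
        raise ValueError(f"unknown noise model: {noise_model!r}")
    rng = np.random.default_rng(seed)
    lo, hi = np.log(omega_range[0]), np.log(omega_range[1])
    omegas = np.exp(rng.uniform(lo, hi, size=n_lines))
    ds = SyntheticDataset(metadata={
        "kind": "invitro_like", "law": law, "C": C, "delta": delta,
        "noise_sd": noise_sd, "noise_model": noise_model, "seed": seed,
    })
    for i, omega in enumerate(omegas):
        lam = C / omega
        for u0 in confluence_grid:
            t_end = _time_to_saturation(law, u0, lam, omega, delta)
            times = np.linspace(0.0, t_end, n_points)
            u = _solution(law, times, u0, lam, omega, delta)
            if noise_sd > 0:
                z = rng.standard_normal(n_points)
                if noise_model == "lognormal":
                    u = u * np.exp(noise_sd * z)
                else:
                    u = u + noise_sd * z
            u = np.clip(u, 1e-6, 1.0)
            ds.series.append({
                "line_id": f"line{i + 1}",
                "initial_confluence": float(u0),
                "times": times, "densities": u,
                "law": law, "lam": float(lam), "omega": float(omega),
                "delta": float(delta), "noise_sd": float(noise_sd),
                "seed": int(seed),
            })
    return ds


def make_abm_dataset(
    u0_grid=(0.01, 0.02, 0.05, 0.1, 0.2, 0.5),
    omega_grid=(4, 8),
    C: float = 0.1,
    delta: float = 0.001,
    reps: int = 5,
    lattice=(64, 64),
    seed: int = 0,
    steps: int | None = None,
) -> SyntheticDataset:
    """Well-mixed ABM density trajectories over (u₀, ω, replicate).

    Every run uses random-confluence seeding, a global migration
    neighborhood at m·Δt = 1, and λ = C/ω; the run length defaults to
    twice the exponential-phase estimate of the time to saturation.
    ω must be one of the named presets {4, 8, 12, 24}.
    """
    width, height = lattice
    ds = SyntheticDataset(metadata={
        "kind": "abm", "C": C, "delta": delta, "lattice": list(lattice),
        "reps": reps, "seed": seed,
    })
    migr = make_neighborhood("global")
    for omega in omega_grid:
        if omega not in _PRESETS:
            raise ValueError(f"omega={omega} has no named preset (use 4, 8, 12 or 24)")
        lam = C / omega
        if lam > 1.0:
            raise ValueError(f"lambda = C/omega = {lam} exceeds 1 per step")
        hood = make_neighborhood(*_PRESETS[omega])
        for u0 in u0_grid:
            if steps is not None:
                n_steps = steps
            elif u0 < 0.95:
                n_steps = max(50, int(2 * np.log(0.95 / u0) / max(lam, 1e-9)) + 1)
            else:
                n_steps = 50
            for rep in range(reps):
                run_seed = seed + 104729 * len(ds.series) + rep
                st = init_state(width, height, "random_confluence", u0=u0,
                                rng=np.random.default_rng(run_seed))
                params = SimParams(
                    birth_rate=lam, death_rate=delta, migration_rate=1.0,
                    birth_hood=hood, migr_hood=migr, steps=n_steps,
                    seed=run_seed + 1,
                )
                traj = simulate(params, st)
                ds.series.append({
                    "line_id": f"omega{omega}",
                    "initial_confluence": float(traj.densities[0]),
                    "times": traj.times.astype(float),
                    "densities": traj.densities,
                    "law": "abm", "lam": float(lam), "omega": float(omega),
                    "delta": float(delta), "noise_sd": 0.0,
                    "seed": int(run_seed),
                })
    return ds
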