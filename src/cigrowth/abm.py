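"""Stochastic on-lattice birth-death-migration simulator.

Cells live on a 2D occupancy lattice, at most one per site.  Each time
step of length Δt sweeps over all live cells in a freshly shuffled
order.  A cell migrates with probability m·Δt (to a uniformly chosen
empty site of its migration neighborhood, or of the whole lattice for a
global neighborhood), then attempts a birth with probability λ·Δt — the
daughter goes to a uniformly chosen empty site of the birth
neighborhood, and the attempt is *blocked* when that neighborhood is
completely occupied (contact inhibition of proliferation).  If no birth
occurred, the cell dies with probability δ·Δt.  Daughters join the sweep
from the next step on.

Rates are interpreted as per-step probabilities with the default Δt = 1,
so λ = 0.1 means a 10% division attempt per cell per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import build_neighbor_table, sweep
from .lattice import LatticeState
from .neighborhoods import NeighborhoodSpec, make_neighborhood

__all__ = ["SimParams", "GrowthTrajectory", "step", "simulate", "ensemble"]


@dataclass
class SimParams:
    """Rates, neighborhoods and schedule of one simulation.

    ``λ·Δt``, ``δ·Δt`` and ``m·Δt`` must each lie in [0, 1] (they are
    per-step event probabilities).
    """

    birth_rate: float = 0.1
    death_rate: float = 0.0
    migration_rate: float = 0.0
    dt: float = 1.0
    birth_hood: NeighborhoodSpec = field(default_factory=lambda: make_neighborhood("moore", 1))
    migr_hood: NeighborhoodSpec = field(default_factory=lambda: make_neighborhood("moore", 1))
    steps: int = 100
    seed: int = 0
    snapshot_every: int | None = None
    death_mode: str = "birth_gated"  # or "independent"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for nm, r in (("birth", self.birth_rate), ("death", self.death_rate),
                      ("migration", self.migration_rate)):
            if r < 0:
                raise ValueError(f"{nm} rate must be nonnegative")
            if r * self.dt > 1.0 + 1e-12:
                raise ValueError(f"{nm} rate × dt exceeds 1 (invalid probability)")
        if self.steps < 1:
            raise ValueError("steps must be positive")
        if self.death_mode not in ("birth_gated", "independent"):
            raise ValueError(f"unknown death_mode: {self.death_mode!r}")


@dataclass
class GrowthTrajectory:
    """Per-step record of one simulation.

    ``times``/``counts``/``densities`` have length steps+1 (index 0 is
    the initial condition); the event arrays log what happened during
    the step ending at each time (zeros at index 0).
    """

    times: np.ndarray
    counts: np.ndarray
    densities: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    moves: np.ndarray
    blocked: np.ndarray
    lattice_size: int
    snapshots: list = field(default_factory=list)


class _Sim:
    """Mutable simulation context wrapping the compiled sweep."""

    def __init__(self, params: SimParams, init: LatticeState):
        self.params = params
        self.state = init.copy()
        w, h = init.width, init.height
        dummy = np.full((w * h, 1), -1, dtype=np.int64)
        self.migr_global = params.migr_hood.global_flag
        self.birth_global = params.birth_hood.global_flag
        self.nbr_migr = (
            dummy if self.migr_global
            else build_neighbor_table(w, h, params.migr_hood.offsets, init.boundary)
        )
        self.nbr_birth = (
            dummy if self.birth_global
            else build_neighbor_table(w, h, params.birth_hood.offsets, init.boundary)
        )
        occ = self.state.occupancy.reshape(-1)
        l = occ.size
        self.occ = occ
        self.cells = np.full(l, -1, dtype=np.int64)
        occupied = np.flatnonzero(occ).astype(np.int64)
        self.n = occupied.size
        self.cells[: self.n] = occupied
        self.empty_list = np.full(l, -1, dtype=np.int64)
        self.empty_pos = np.full(l, -1, dtype=np.int64)
        empties = np.flatnonzero(occ == 0).astype(np.int64)
        self.n_empty = empties.size
        self.empty_list[: self.n_empty] = empties
        self.empty_pos[empties] = np.arange(self.n_empty)
        self.rng = np.random.default_rng(params.seed)

    def step(self):
        p = self.params
        self.n, self.n_empty, b, d, mv, bl = sweep(
            self.occ, self.cells, self.n,
            self.nbr_migr, self.nbr_birth,
            self.migr_global, self.birth_global,
            self.empty_list, self.empty_pos, self.n_empty,
            p.migration_rate * p.dt, p.birth_rate * p.dt, p.death_rate * p.dt,
            p.death_mode == "independent", self.rng,
        )
        # occupancy was updated in place; refresh the cached count
        self.state._n = self.n
        return b, d, mv, bl


def step(state: LatticeState, params: SimParams,
         rng: np.random.Generator | None = None):
    """Advance one step; returns (new state, event-count dict).

    Convenience wrapper around the sweep for single-step use; ``rng``
    overrides the generator seeded from ``params.seed``.
    """
    sim = _Sim(params, state)
    if rng is not None:
        sim.rng = rng
    b, d, mv, bl = sim.step()
    new = LatticeState(sim.occ.reshape(state.occupancy.shape).copy(), state.boundary)
    return new, {"births": b, "deaths": d, "moves": mv, "blocked": bl}


def simulate(params: SimParams, init: LatticeState) -> GrowthTrajectory:
    """Run the full simulation; identical (seed, params, init) reproduce
    the trajectory exactly."""
    sim = _Sim(params, init)
    steps = params.steps
    counts = np.empty(steps + 1, dtype=np.int64)
    ev = np.zeros((4, steps + 1), dtype=np.int64)
    counts[0] = sim.n
    snapshots = []
    snap = params.snapshot_every
    if snap:
        snapshots.append((0.0, _snapshot(sim, init)))
    for t in range(1, steps + 1):
        ev[:, t] = sim.step()
        counts[t] = sim.n
        if snap and t % snap == 0:
            snapshots.append((t * params.dt, _snapshot(sim, init)))
    times = np.arange(steps + 1) * params.dt
    l = init.occupancy.size
    return GrowthTrajectory(
        times=times, counts=counts, densities=counts / l,
        births=ev[0], deaths=ev[1], moves=ev[2], blocked=ev[3],
        lattice_size=l, snapshots=snapshots,
    )


def _snapshot(sim: _Sim, init: LatticeState) -> LatticeState:
    return LatticeState(sim.occ.reshape(init.occupancy.shape).copy(), init.boundary)


def ensemble(params: SimParams, init: LatticeState, reps: int, base_seed: int | None = None):
    """Run ``reps`` replicates with consecutive seeds.

    Returns (mean counts, std counts, list of trajectories); the mean
    and population-std are taken per time point across replicates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    trajs = []
    for r in range(reps):
        p = SimParams(**{**params.__dict__, "seed": base_seed + r})
        trajs.append(simulate(p, init))
    allc = np.stack([t.counts for t in trajs]).astype(float)
    return allc.mean(axis=0), allc.std(axis=0), trajs
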