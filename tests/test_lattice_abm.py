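import numpy as np
import pytest
from scipy.ndimage import label

from cigrowth import (SimParams, ensemble, init_state, make_neighborhood,
                      simulate, step)
from cigrowth.lattice import LatticeState, SeedingError


class TestInitState:
    def test_single_center(self):
        st = init_state(201, 201, "single_center")
        assert st.n == 1
        assert st.occupancy[100, 100] == 1

    def test_random_count_exact(self):
        st = init_state(10, 10, "random_count", n0=37,
                        rng=np.random.default_rng(0))
        assert st.n == 37

    def test_saturated_and_empty(self):
        assert init_state(10, 10, "random_count", n0=100,
                          rng=np.random.default_rng(0)).n == 100
        assert init_state(10, 10, "random_count", n0=0,
                          rng=np.random.default_rng(0)).n == 0

    def test_overfull_rejected(self):
        with pytest.raises(SeedingError):
            init_state(10, 10, "random_count", n0=101,
                       rng=np.random.default_rng(0))

    def test_random_confluence_rounding(self):
        st = init_state(10, 10, "random_confluence", u0=0.25,
                        rng=np.random.default_rng(1))
        assert st.n == 25

    def test_binary_occupancy_enforced(self):
        with pytest.raises(ValueError):
            LatticeState(np.full((3, 3), 2, dtype=np.uint8))


class TestStep:
    def test_zero_rates_noop(self):
        st = init_state(10, 10, "random_count", n0=30,
                        rng=np.random.default_rng(2))
        new, events = step(st, SimParams(birth_rate=0.0, death_rate=0.0,
                                         migration_rate=0.0, steps=1))
        assert np.array_equal(new.occupancy, st.occupancy)
        assert all(v == 0 for v in events.values())

    def test_full_lattice_all_births_blocked(self):
        st = init_state(6, 6, "random_count", n0=36,
                        rng=np.random.default_rng(0))
        new, events = step(st, SimParams(birth_rate=1.0, death_rate=0.0,
                                         migration_rate=0.0, steps=1))
        assert events["blocked"] == 36 and events["births"] == 0
        assert new.n == 36

    def test_certain_death(self):
        st = init_state(5, 5, "single_center")
        new, events = step(st, SimParams(birth_rate=0.0, death_rate=1.0,
                                         migration_rate=0.0, steps=1))
        assert new.n == 0 and events["deaths"] == 1

    def test_death_gated_on_successful_birth(self):
        # λΔt = δΔt = 1 on a lone cell with room: birth always succeeds,
        # so the default flowchart gating forbids the death
        st = init_state(5, 5, "single_center")
        new, events = step(st, SimParams(birth_rate=1.0, death_rate=1.0,
                                         migration_rate=0.0, steps=1))
        assert events["births"] == 1 and events["deaths"] == 0
        assert new.n == 2

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimParams(birth_rate=1.5, dt=1.0)


class TestSimulate:
    def test_conservation_without_rates(self):
        st = init_state(10, 10, "random_count", n0=5,
                        rng=np.random.default_rng(3))
        traj = simulate(SimParams(birth_rate=0.0, death_rate=0.0,
                                  migration_rate=0.0, steps=100), st)
        assert np.all(traj.counts == 5)

    def test_count_balance_equals_births_minus_deaths(self):
        st = init_state(32, 32, "random_count", n0=50,
                        rng=np.random.default_rng(4))
        traj = simulate(SimParams(birth_rate=0.1, death_rate=0.05,
                                  migration_rate=0.3, steps=200, seed=7), st)
        dn = np.diff(traj.counts)
        assert np.array_equal(dn, (traj.births - traj.deaths)[1:])
        assert np.allclose(traj.densities, traj.counts / traj.lattice_size)

    def test_seed_determinism(self):
        st = init_state(32, 32, "random_count", n0=20,
                        rng=np.random.default_rng(5))
        p = SimParams(birth_rate=0.1, death_rate=0.01, migration_rate=0.5,
                      steps=150, seed=11)
        a, b = simulate(p, st), simulate(p, st)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.blocked, b.blocked)

    def test_saturation_absorbing_without_death(self):
        st = init_state(16, 16, "random_count", n0=10,
                        rng=np.random.default_rng(6))
        traj = simulate(SimParams(birth_rate=0.5, death_rate=0.0,
                                  migration_rate=0.0, steps=400, seed=1), st)
        assert np.all(np.diff(traj.counts) >= 0)
        assert traj.counts[-1] == 256
        sat = np.argmax(traj.counts == 256)
        assert np.all(traj.counts[sat:] == 256)

    def test_global_birth_hood_matches_exponential_recursion(self):
        # δ=0, global birth neighborhood, λΔt=0.1: E[n_{t+1}] = 1.1 E[n_t]
        # while the lattice is far from saturation
        steps, reps = 40, 20
        finals = []
        for s in range(reps):
            st = init_state(32, 32, "single_center")
            traj = simulate(SimParams(birth_rate=0.1, death_rate=0.0,
                                      migration_rate=0.0,
                                      birth_hood=make_neighborhood("global"),
                                      steps=steps, seed=900 + s), st)
            finals.append(traj.counts[-1])
        finals = np.asarray(finals, dtype=float)
        expected = 1.1 ** steps
        se = finals.std(ddof=1) / np.sqrt(reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_moore_growth_stays_8_connected(self):
        # lattice large enough that the cluster never wraps the boundary
        st = init_state(128, 128, "single_center")
        traj = simulate(SimParams(birth_rate=0.3, migration_rate=0.0,
                                  birth_hood=make_neighborhood("moore", 1),
                                  steps=100, seed=8, snapshot_every=20), st)
        for _, snap in traj.snapshots:
            _, ncomp = label(snap.occupancy, structure=np.ones((3, 3)))
            assert ncomp == 1


class TestEnsemble:
    def test_single_rep_degenerate(self):
        st = init_state(16, 16, "random_count", n0=8,
                        rng=np.random.default_rng(7))
        p = SimParams(birth_rate=0.1, steps=50, seed=3)
        mean, std, trajs = ensemble(p, st, reps=1)
        assert np.array_equal(mean, trajs[0].counts)
        assert np.all(std == 0)

    def test_deterministic_case_zero_std(self):
        st = init_state(16, 16, "random_count", n0=8,
                        rng=np.random.default_rng(8))
        p = SimParams(birth_rate=0.0, death_rate=0.0, migration_rate=0.0,
                      steps=20)
        _, std, _ = ensemble(p, st, reps=5)
        assert np.all(std == 0)

    def test_larger_birth_hood_grows_faster_without_migration(self):
        st = init_state(64, 64, "single_center")
        means = {}
        for order in (1, 2):
            p = SimParams(birth_rate=0.1, migration_rate=0.0,
                          birth_hood=make_neighborhood("moore", order),
                          steps=150, seed=40)
            means[order], _, _ = ensemble(p, st, reps=20)
        assert means[2][-1] > means[1][-1]

    def test_periodic_translation_invariance_of_mean_growth(self):
        # with periodic boundaries, a centered and an off-center seed give
        # statistically identical count trajectories
        finals = {}
        for name, (x, y) in [("center", (16, 16)), ("corner", (2, 3))]:
            vals = []
            for s in range(12):
                grid = np.zeros((32, 32), dtype=np.uint8)
                grid[y, x] = 1
                p = SimParams(birth_rate=0.1, migration_rate=0.0,
                              birth_hood=make_neighborhood("moore", 1),
                              steps=120, seed=600 + s)
                vals.append(simulate(p, LatticeState(grid, "periodic")).counts[-1])
            finals[name] = np.asarray(vals, dtype=float)
        se = np.hypot(finals["center"].std(ddof=1) / np.sqrt(12),
                      finals["corner"].std(ddof=1) / np.sqrt(12))
        assert abs(finals["center"].mean() - finals["corner"].mean()) < 3 * se


def test_high_migration_mean_matches_meanfield_map():
    """Global migration at m·Δt=1 suppresses spatial correlations: the
    ensemble-mean density follows the well-mixed mean-field update
    u' = u + λΔt·u(1 − u^ω) within 5% through the growth phase."""
    steps, reps, omega, lam = 60, 20, 8, 0.1
    dens = []
    for s in range(reps):
        st = init_state(64, 64, "random_confluence", u0=0.05,
                        rng=np.random.default_rng(800 + s))
        p = SimParams(birth_rate=lam, death_rate=0.0, migration_rate=1.0,
                      birth_hood=make_neighborhood("moore", 1),
                      migr_hood=make_neighborhood("global"),
                      steps=steps, seed=700 + s)
        dens.append(simulate(p, st).densities)
    mean = np.mean(dens, axis=0)
    u = np.empty(steps + 1)
    u[0] = mean[0]
    for t in range(steps):
        u[t + 1] = u[t] + lam * u[t] * (1.0 - u[t] ** omega)
    rel = np.abs(mean - u) / u
    assert rel[u <= 0.95].max() < 0.05
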