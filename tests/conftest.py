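import numpy as np
import pytest

from cigrowth import SimParams, init_state, make_neighborhood, simulate


@pytest.fixture(scope="session")
def radial_run():
    """Single-seed, no-migration run on 256² with Von Neumann birth:
    the radially expanding cluster used by several spatial checks."""
    params = SimParams(
        birth_rate=0.1, migration_rate=0.0,
        birth_hood=make_neighborhood("von_neumann", 1),
        steps=900, seed=3, snapshot_every=100,
    )
    return params, simulate(params, init_state(256, 256, "single_center"))


@pytest.fixture(scope="session")
def wellmixed_runs():
    """Five well-mixed (global migration, m·Δt=1) growth runs per birth
    neighborhood ω ∈ {4, 8} on 64², with snapshots; shared by the
    occupancy-consistency checks."""
    out = {}
    for omega, (nm, order), lam in [(4, ("von_neumann", 1), 0.025),
                                    (8, ("moore", 1), 0.0125)]:
        runs = []
        for s in range(5):
            params = SimParams(
                birth_rate=lam, death_rate=0.0, migration_rate=1.0,
                birth_hood=make_neighborhood(nm, order),
                migr_hood=make_neighborhood("global"),
                steps=700, seed=100 + s, snapshot_every=25,
            )
            init = init_state(64, 64, "random_confluence", u0=0.02,
                              rng=np.random.default_rng(200 + s))
            runs.append((params, simulate(params, init)))
        out[omega] = runs
    return out
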