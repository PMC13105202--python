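"""Binary occupancy lattice.

Coordinates are 0-based ``(x, y) = (column, row)``, origin top-left.
Internally the grid is stored row-major as ``occupancy[y, x]`` with
values in {0, 1}: at most one cell per site (volume exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LatticeState", "init_state", "SeedingError"]


class SeedingError(ValueError):
    """Raised when the requested initial population does not fit the lattice."""


@dataclass
class LatticeState:
    """Occupancy grid with a boundary-condition mode.

    Attributes
    ----------
    occupancy : (height, width) uint8 array of {0, 1}
    boundary : {"periodic", "fixed"}
        Periodic wraps neighborhoods; fixed truncates them at the edges
        (boundary cells see fewer neighbor sites).
    """

    occupancy: np.ndarray
    boundary: str = "periodic"
    _n: int = field(default=-1, repr=False)

    def __post_init__(self):
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be a 2D grid")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        if self.boundary not in ("periodic", "fixed"):
            raise ValueError(f"unknown boundary mode: {self.boundary!r}")
        self._n = int(self.occupancy.sum())

    @property
    def height(self) -> int:
        return self.occupancy.shape[0]

    @property
    def width(self) -> int:
        return self.occupancy.shape[1]

    @property
    def l(self) -> int:
        """Total number of lattice sites."""
        return self.occupancy.size

    @property
    def n(self) -> int:
        """Number of occupied sites (cached)."""
        return self._n

    @property
    def density(self) -> float:
        return self._n / self.l

    def occupied_sites(self) -> np.ndarray:
        """Occupied coordinates as an (n, 2) array of (x, y), row-major order."""
        ys, xs = np.nonzero(self.occupancy)
        return np.column_stack([xs, ys])

    def copy(self) -> "LatticeState":
        return LatticeState(self.occupancy.copy(), self.boundary)


def init_state(
    width: int,
    height: int,
    seeding: str = "single_center",
    *,
    n0: int | None = None,
    u0: float | None = None,
    boundary: str = "periodic",
    rng: np.random.Generator | None = None,
) -> LatticeState:
    """Create an initial lattice state.

    Parameters
    ----------
    seeding : {"single_center", "random_count", "random_confluence"}
        ``single_center`` places one cell at (⌊width/2⌋, ⌊height/2⌋);
        ``random_count`` places exactly ``n0`` cells uniformly without
        replacement; ``random_confluence`` places ``round(u0·l)`` cells.
    """
    if width < 1 or height < 1:
        raise ValueError("lattice dimensions must be positive")
    grid = np.zeros((height, width), dtype=np.uint8)
    l = width * height
    if seeding == "single_center":
        grid[height // 2, width // 2] = 1
    elif seeding in ("random_count", "random_confluence"):
        if seeding == "random_confluence":
            if u0 is None or not (0.0 <= u0 <= 1.0):
                raise SeedingError("random_confluence requires u0 in [0, 1]")
            n0 = int(round(u0 * l))
        if n0 is None or n0 < 0:
            raise SeedingError("random_count requires a nonnegative n0")
        if n0 > l:
            raise SeedingError(f"cannot place {n0} cells on {l} sites")
        if rng is None:
            rng = np.random.default_rng()
        sites = rng.choice(l, size=n0, replace=False)
        grid.flat[sites] = 1
    else:
        raise SeedingError(f"unknown seeding mode: {seeding!r}")
    return LatticeState(grid, boundary)
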