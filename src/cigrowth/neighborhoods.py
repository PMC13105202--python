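"""Lattice neighborhood presets.

A neighborhood is the set of relative lattice displacements into which a
cell may place a daughter (birth neighborhood, size ω) or move (migration
neighborhood, size ϕ).  The named presets are the four standard 2D
paradigms: Von Neumann (ω=4), Moore (ω=8), second-order Von Neumann
(ω=12) and second-order Moore (ω=24).  A ``global`` neighborhood stands
for "every other lattice site" and models a well-mixed population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["NeighborhoodSpec", "make_neighborhood", "UnknownNeighborhoodError"]


class UnknownNeighborhoodError(ValueError):
    """Raised for an unrecognized neighborhood name or unsupported order."""


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A set of relative site offsets.

    Attributes
    ----------
    name : str
        Preset identifier, e.g. ``"moore"``.
    order : int
        Neighborhood order (radius class), 1 or 2 for named presets.
    offsets : tuple of (int, int)
        Unique ``(dx, dy)`` displacements; never contains the origin.
    size : int
        ω = number of offsets (0 for the global neighborhood, whose size
        depends on the lattice: every other site).
    global_flag : bool
        True if the neighborhood is all other lattice sites.
    """

    name: str
    order: int
    offsets: tuple = field(default_factory=tuple)
    global_flag: bool = False

    def __post_init__(self):
        if (0, 0) in self.offsets:
            raise ValueError("neighborhood offsets must not contain the origin")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("neighborhood offsets must be unique")

    @property
    def size(self) -> int:
        return len(self.offsets)

    def __str__(self) -> str:  # e.g. "moore:1" / "global"
        return self.name if self.global_flag else f"{self.name}:{self.order}"


def _von_neumann(order: int):
    # all sites with Manhattan distance 1..order
    return tuple(
        (dx, dy)
        for dx in range(-order, order + 1)
        for dy in range(-order, order + 1)
        if 0 < abs(dx) + abs(dy) <= order
    )


def _moore(order: int):
    # all sites with Chebyshev distance 1..order
    return tuple(
        (dx, dy)
        for dx in range(-order, order + 1)
        for dy in range(-order, order + 1)
        if (dx, dy) != (0, 0)
    )


def make_neighborhood(name: str, order: int = 1) -> NeighborhoodSpec:
    """Build a neighborhood preset.

    Parameters
    ----------
    name : {"von_neumann", "moore", "global"}
    order : {1, 2}
        Ignored for ``"global"``.

    Returns
    -------
    NeighborhoodSpec
        Sizes are 4, 8 (order 1) and 12, 24 (order 2) for von_neumann
        and moore respectively.
    """
    name = name.lower().replace("-", "_")
    if name == "global":
        return NeighborhoodSpec(name="global", order=0, offsets=(), global_flag=True)
    if name not in ("von_neumann", "moore"):
        raise UnknownNeighborhoodError(f"unknown neighborhood name: {name!r}")
    if order not in (1, 2):
        raise UnknownNeighborhoodError(
            f"unsupported order {order!r} for preset {name!r} (use 1 or 2)"
        )
    offsets = _von_neumann(order) if name == "von_neumann" else _moore(order)
    return NeighborhoodSpec(name=name, order=order, offsets=offsets)


def parse_neighborhood(text: str) -> NeighborhoodSpec:
    """Parse ``"moore:1"``-style strings (``"global"`` allowed)."""
    text = text.strip()
    if ":" in text:
        name, order = text.split(":", 1)
        return make_neighborhood(name, int(order))
    return make_neighborhood(text)
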