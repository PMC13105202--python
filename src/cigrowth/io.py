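"""CSV/JSON/YAML I/O for trajectories, snapshots and results.

Conventions: trajectory CSV has header
``time,count,density,births,deaths,moves,blocked`` (one row per step,
row 0 the initial condition); snapshot CSV has header ``x,y`` listing
occupied sites with 0-based (column, row) coordinates, origin top-left,
in row-major order.  Floats are written with 17 significant digits so
read(write(x)) round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abm import GrowthTrajectory
from .lattice import LatticeState

__all__ = [
    "read_series",
    "write_series",
    "read_snapshot",
    "write_snapshot",
    "write_json",
    "load_config",
    "write_provenance",
]

_FLOAT_FMT = "%.17g"


class SeriesFormatError(ValueError):
    """Raised for malformed series files."""


def read_series(path, lattice_size: int | None = None):
    """Read a time series CSV.

    Requires a ``time`` column and at least one of ``density`` /
    ``count``; a count-only file needs ``lattice_size`` to derive
    densities.  Returns ``(times, densities, counts)`` sorted by time
    (counts is None when absent); duplicate times and out-of-range
    densities are rejected.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "time" not in cols:
        raise SeriesFormatError(f"{path}: missing 'time' column")
    if not ({"density", "count"} & cols):
        raise SeriesFormatError(f"{path}: need a 'density' or 'count' column")
    for c in ("time", "density", "count"):
        if c in cols and not np.issubdtype(df[c].dtype, np.number):
            raise SeriesFormatError(f"{path}: non-numeric entries in '{c}'")
    df = df.sort_values("time", kind="stable")
    times = df["time"].to_numpy(dtype=float)
    if np.unique(times).size != times.size:
        raise SeriesFormatError(f"{path}: duplicate time points")
    counts = df["count"].to_numpy(dtype=float) if "count" in cols else None
    if "density" in cols:
        densities = df["density"].to_numpy(dtype=float)
    else:
        if lattice_size is None:
            raise SeriesFormatError(
                f"{path}: count-only file requires the lattice size to derive density")
        densities = counts / lattice_size
    if np.any((densities < 0) | (densities > 1)):
        raise SeriesFormatError(f"{path}: densities outside [0, 1]")
    return times, densities, counts


def write_series(traj: GrowthTrajectory, path):
    """Write a trajectory CSV (see module docstring for the schema)."""
    df = pd.DataFrame({
        "time": traj.times, "count": traj.counts, "density": traj.densities,
        "births": traj.births, "deaths": traj.deaths,
        "moves": traj.moves, "blocked": traj.blocked,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_snapshot(state: LatticeState, path):
    """Write occupied sites as an ``x,y`` CSV (header always present)."""
    sites = state.occupied_sites()
    pd.DataFrame({"x": sites[:, 0], "y": sites[:, 1]}).to_csv(path, index=False)


def read_snapshot(path, width: int, height: int, boundary: str = "periodic") -> LatticeState:
    """Read an ``x,y`` occupied-site list back into a LatticeState."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise SeriesFormatError(f"{path}: snapshot needs 'x' and 'y' columns")
    grid = np.zeros((height, width), dtype=np.uint8)
    xs = df["x"].to_numpy(dtype=int)
    ys = df["y"].to_numpy(dtype=int)
    if xs.size and (xs.min() < 0 or xs.max() >= width or ys.min() < 0 or ys.max() >= height):
        raise SeriesFormatError(f"{path}: coordinates outside the {width}×{height} lattice")
    grid[ys, xs] = 1
    return LatticeState(grid, boundary)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(results: dict, path):
    """Write results as pretty JSON (numpy types converted)."""
    Path(path).write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a flat dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:16]


def write_provenance(config: dict, out_path, seed=None):
    """Write a provenance record (config + package version + seed + hash)
    next to an output file."""
    from . import __version__
    record = {
        "config": _jsonable(config),
        "config_hash": config_hash(config),
        "version": __version__,
        "seed": seed,
    }
    p = Path(out_path)
    write_json(record, p.with_name(p.stem + ".provenance.json"))
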