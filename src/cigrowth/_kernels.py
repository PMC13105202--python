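"""Compiled inner loops for the lattice birth-death-migration process.

The sweep visits every occupied site in a freshly shuffled order and, per
cell: (1) migration attempt, (2) birth attempt into the birth
neighborhood (blocked if fully occupied), (3) death attempt, by default
only when no successful birth occurred.  Daughters placed during a sweep
are not iterated until the next sweep.  A flat empty-site list with an
index map gives O(1) site bookkeeping, which also serves the global
(well-mixed) migration neighborhood.

All randomness flows through one ``np.random.Generator`` passed in from
the caller; draws happen in a fixed order (shuffle, then per cell:
migration uniform, site choice, birth uniform, site choice, death
uniform — a uniform is drawn only when the corresponding rate is
positive), so trajectories are reproducible bit-for-bit from the seed.
"""

import numpy as np
from numba import njit

__all__ = ["build_neighbor_table", "sweep"]


def build_neighbor_table(width, height, offsets, boundary):
    """Flat-index neighbor table, shape (l, ω); -1 marks truncated sites.

    Offsets are (dx, dy) with x = column, y = row; flat index = y*width + x.
    """
    offs = np.asarray(offsets, dtype=np.int64).reshape(-1, 2)
    l = width * height
    table = np.full((l, offs.shape[0]), -1, dtype=np.int64)
    ys, xs = np.divmod(np.arange(l), width)
    for k, (dx, dy) in enumerate(offs):
        nx, ny = xs + dx, ys + dy
        if boundary == "periodic":
            table[:, k] = (ny % height) * width + (nx % width)
        else:
            ok = (0 <= nx) & (nx < width) & (0 <= ny) & (ny < height)
            table[ok, k] = ny[ok] * width + nx[ok]
    return table


@njit(cache=True)
def _empty_remove(site, empty_list, empty_pos, n_empty):
    k = empty_pos[site]
    last = empty_list[n_empty - 1]
    empty_list[k] = last
    empty_pos[last] = k
    empty_pos[site] = -1
    return n_empty - 1


@njit(cache=True)
def _empty_add(site, empty_list, empty_pos, n_empty):
    empty_list[n_empty] = site
    empty_pos[site] = n_empty
    return n_empty + 1


@njit(cache=True)
def _pick_empty_neighbor(site, occ, nbr, rng, buf):
    """Uniform choice among empty neighbors of ``site``; -1 if none."""
    cnt = 0
    for k in range(nbr.shape[1]):
        t = nbr[site, k]
        if t >= 0 and occ[t] == 0:
            buf[cnt] = t
            cnt += 1
    if cnt == 0:
        return np.int64(-1)
    return buf[rng.integers(0, cnt)]


@njit(cache=True)
def sweep(
    occ,
    cells,
    n,
    nbr_migr,
    nbr_birth,
    migr_global,
    birth_global,
    empty_list,
    empty_pos,
    n_empty,
    p_m,
    p_b,
    p_d,
    death_independent,
    rng,
):
    """One synchronous-sweep time step; returns (n, n_empty, events).

    ``cells[:n]`` holds the flat sites of live cells and is updated in
    place; events = (births, deaths, moves, blocked birth attempts).
    """
    # Fisher-Yates shuffle of the live cells
    for i in range(n - 1, 0, -1):
        j = rng.integers(0, i + 1)
        cells[i], cells[j] = cells[j], cells[i]

    births = 0
    deaths = 0
    moves = 0
    blocked = 0
    n_new = 0
    newborn = np.empty(n if n > 0 else 1, dtype=np.int64)
    buf = np.empty(max(nbr_migr.shape[1], nbr_birth.shape[1], 1), dtype=np.int64)

    for i in range(n):
        s = cells[i]

        # --- migration ---
        if p_m > 0.0 and rng.random() < p_m:
            if migr_global:
                t = empty_list[rng.integers(0, n_empty)] if n_empty > 0 else np.int64(-1)
            else:
                t = _pick_empty_neighbor(s, occ, nbr_migr, rng, buf)
            if t >= 0:
                occ[s] = 0
                occ[t] = 1
                n_empty = _empty_remove(t, empty_list, empty_pos, n_empty)
                n_empty = _empty_add(s, empty_list, empty_pos, n_empty)
                cells[i] = t
                s = t
                moves += 1

        # --- birth (blocked when the birth neighborhood is full) ---
        born = False
        if p_b > 0.0 and rng.random() < p_b:
            if birth_global:
                t = empty_list[rng.integers(0, n_empty)] if n_empty > 0 else np.int64(-1)
            else:
                t = _pick_empty_neighbor(s, occ, nbr_birth, rng, buf)
            if t >= 0:
                occ[t] = 1
                n_empty = _empty_remove(t, empty_list, empty_pos, n_empty)
                newborn[n_new] = t
                n_new += 1
                births += 1
                born = True
            else:
                blocked += 1

        # --- death (gated on no birth unless decoupled) ---
        if (death_independent or not born) and p_d > 0.0 and rng.random() < p_d:
            occ[s] = 0
            n_empty = _empty_add(s, empty_list, empty_pos, n_empty)
            cells[i] = -1
            deaths += 1

    # compact survivors, then append this step's daughters
    w = 0
    for i in range(n):
        if cells[i] >= 0:
            cells[w] = cells[i]
            w += 1
    for i in range(n_new):
        cells[w] = newborn[i]
        w += 1

    return w, n_empty, births, deaths, moves, blocked
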