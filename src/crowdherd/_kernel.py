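"""Compiled inner loop for whole-generation simulation.

This module holds the numba-jitted kernel that advances a population
through the T asynchronous time steps of one generation.  It implements
exactly the same rules, in exactly the same random-draw order, as the
pure-Python path built from :mod:`crowdherd.lattice` /
:mod:`crowdherd.genotype` primitives — the two are cross-checked for
trajectory equality in the test suite.  All randomness is consumed from a
pre-generated ``(T, 4, n)`` uniform block (per step: order keys, noise
input, squeeze test, tie-break; indexed by agent id).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_generation_kernel", "moore_count"]


@njit(cache=True, inline="always")
def moore_count(grid, x, y, r):
    """Occupied-cell count in the radius-r Moore window around (x, y)."""
    height, width = grid.shape
    c = 0
    for dy in range(-r, r + 1):
        yy = y + dy
        if yy < 0:
            yy += height
        elif yy >= height:
            yy -= height
        for dx in range(-r, r + 1):
            if dx == 0 and dy == 0:
                continue
            xx = x + dx
            if xx < 0:
                xx += width
            elif xx >= width:
                xx -= width
            if grid[yy, xx] >= 0:
                c += 1
    return c


@njit(cache=True)
def run_generation_kernel(
    grid,
    posx,
    posy,
    weights,
    p_transit,
    r,
    draws,
    neighbour_sum,
    transitions,
    occasions,
    moves,
    traj,
    nrec,
    check_invariants,
):
    """Advance all agents through ``T = draws.shape[0]`` time steps.

    Parameters
    ----------
    grid : (H, W) int32
        Occupancy map, -1 vacant else agent id; updated in place.
    posx, posy : (n,) int64
        Agent coordinates, updated in place.
    weights : (n, 11, 4) float64
        Genotype weight tables.
    p_transit : float
        Squeeze-through probability on an occupied target.
    r : int
        Moore-neighbourhood radius.
    draws : (T, 4, n) float64
        Uniform variates (order keys / noise / squeeze / tie-break).
    neighbour_sum : (n,) float64
        Accumulates the settled neighbourhood size per step (in place).
    transitions : (n,) int64
        Accumulates settled-position changes between consecutive steps
        (T - 1 possible events; in place).
    occasions, moves : (window_max + 1,) int64
        Conditional-leave tallies: for each settled neighbourhood size n
        at step t, ``occasions[n]`` counts the t -> t+1 transitions and
        ``moves[n]`` those whose settled position changed (in place).
    traj : (T, n, 2) int64
        Settled (x, y) position records, one row per step (in place).
    nrec : (T, n) int64
        Settled neighbourhood-size records, one row per step (in place).
    check_invariants : bool
        When True, verify occupancy/position consistency after every
        step (used by the conservation test suite).

    Returns
    -------
    int
        0 on success; ``-(t + 1)`` if an invariant check failed after
        step ``t``.
    """
    height, width = grid.shape
    n_agents = posx.shape[0]
    n_steps = draws.shape[0]
    window_max = (2 * r + 1) ** 2 - 1
    inv = 1.0 / window_max

    # direction offsets in fixed N, S, E, W order
    dxs = np.array([0, 0, 1, -1], dtype=np.int64)
    dys = np.array([-1, 1, 0, 0], dtype=np.int64)

    out = np.empty(4, dtype=np.float64)
    tie_buf = np.empty(4, dtype=np.int64)
    prev_x = np.empty(n_agents, dtype=np.int64)
    prev_y = np.empty(n_agents, dtype=np.int64)
    prev_n = np.empty(n_agents, dtype=np.int64)

    for t in range(n_steps):
        order = np.argsort(draws[t, 0])
        for k in range(n_agents):
            i = order[k]
            x = posx[i]
            y = posy[i]
            w = weights[i]
            noise = draws[t, 1, i]
            # outputs: weighted sums over the 11-slot percept
            for o in range(4):
                acc = 0.0
                for d in range(4):
                    tx = x + dxs[d]
                    if tx < 0:
                        tx += width
                    elif tx >= width:
                        tx -= width
                    ty = y + dys[d]
                    if ty < 0:
                        ty += height
                    elif ty >= height:
                        ty -= height
                    occ = 1.0 if grid[ty, tx] >= 0 else 0.0
                    acc += occ * w[d, o]
                    acc += moore_count(grid, tx, ty, r) * inv * w[4 + d, o]
                acc += moore_count(grid, x, y, r) * inv * w[8, o]
                acc += noise * w[9, o]
                acc += w[10, o]
                out[o] = acc
            best = out[0]
            for o in range(1, 4):
                if out[o] > best:
                    best = out[o]
            ntied = 0
            for o in range(4):
                if out[o] == best:
                    tie_buf[ntied] = o
                    ntied += 1
            if ntied == 1:
                d = tie_buf[0]
            else:
                d = tie_buf[int(draws[t, 3, i] * ntied)]
            tx = x + dxs[d]
            if tx < 0:
                tx += width
            elif tx >= width:
                tx -= width
            ty = y + dys[d]
            if ty < 0:
                ty += height
            elif ty >= height:
                ty -= height
            target = grid[ty, tx]
            if target < 0:
                grid[y, x] = -1
                grid[ty, tx] = i
                posx[i] = tx
                posy[i] = ty
            elif draws[t, 2, i] < p_transit:
                grid[y, x] = target
                grid[ty, tx] = i
                posx[target] = x
                posy[target] = y
                posx[i] = tx
                posy[i] = ty
        # settle: record neighbourhood sizes and t-1 -> t transitions
        for i in range(n_agents):
            nsize = moore_count(grid, posx[i], posy[i], r)
            neighbour_sum[i] += nsize
            traj[t, i, 0] = posx[i]
            traj[t, i, 1] = posy[i]
            nrec[t, i] = nsize
            if t > 0:
                occasions[prev_n[i]] += 1
                if posx[i] != prev_x[i] or posy[i] != prev_y[i]:
                    moves[prev_n[i]] += 1
                    transitions[i] += 1
            prev_n[i] = nsize
            prev_x[i] = posx[i]
            prev_y[i] = posy[i]
        if check_invariants:
            occupied = 0
            for yy in range(height):
                for xx in range(width):
                    a = grid[yy, xx]
                    if a >= 0:
                        occupied += 1
                        if posx[a] != xx or posy[a] != yy:
                            return -(t + 1)
            if occupied != n_agents:
                return -(t + 1)
    return 0
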