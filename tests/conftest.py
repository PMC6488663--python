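"""Shared fixtures and independent brute-force oracles.

The oracles re-implement the model rules from scratch on plain Python
dictionaries/lists — no shared code with the package's simulation paths —
and consume the same pre-drawn uniform blocks, so trajectory comparisons
are exact.
"""

from __future__ import annotations

import numpy as np
import pytest

OFFSETS = [(0, -1), (0, 1), (1, 0), (-1, 0)]  # N, S, E, W


def brute_force_count(occupied, x, y, width, height, r=1):
    """Independent Moore-window recount over all (2r+1)^2 - 1 offsets."""
    c = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx == 0 and dy == 0:
                continue
            if ((x + dx) % width, (y + dy) % height) in occupied:
                c += 1
    return c


def oracle_decide(weights, percept, tie_u):
    """Independent argmax readout: explicit weighted sums, first-max ties
    collected in ascending direction order, tie broken by u."""
    outs = []
    for o in range(4):
        s = 0.0
        for i in range(11):
            s += percept[i] * weights[i][o]
        outs.append(s)
    best = max(outs)
    tied = [o for o in range(4) if outs[o] == best]
    return tied[int(tie_u * len(tied))]


def oracle_simulate(width, height, init_pos, weights, n_steps, p_transit, r, draws):
    """Straight-line re-simulation of the interaction rules.

    ``draws`` is the (T, 4, n) uniform block (order keys, noise, squeeze,
    tie-break, indexed by agent id).  Returns settled trajectories
    (T, n, 2) and settled neighbourhood sizes (T, n).
    """
    n = len(init_pos)
    pos = [tuple(map(int, p)) for p in init_pos]
    occupied = {pos[i]: i for i in range(n)}
    assert len(occupied) == n
    window_max = (2 * r + 1) ** 2 - 1
    traj = np.empty((n_steps, n, 2), dtype=np.int64)
    nrec = np.empty((n_steps, n), dtype=np.int64)
    for t in range(n_steps):
        order = sorted(range(n), key=lambda i: draws[t, 0, i])
        for i in order:
            x, y = pos[i]
            percept = []
            for dx, dy in OFFSETS:
                cell = ((x + dx) % width, (y + dy) % height)
                percept.append(1.0 if cell in occupied else 0.0)
            for dx, dy in OFFSETS:
                cx, cy = (x + dx) % width, (y + dy) % height
                percept.append(
                    brute_force_count(occupied, cx, cy, width, height, r)
                    / window_max
                )
            percept.append(
                brute_force_count(occupied, x, y, width, height, r) / window_max
            )
            percept.append(float(draws[t, 1, i]))
            percept.append(1.0)
            d = oracle_decide(weights[i], percept, float(draws[t, 3, i]))
            dx, dy = OFFSETS[d]
            target = ((x + dx) % width, (y + dy) % height)
            if target not in occupied:
                del occupied[(x, y)]
                occupied[target] = i
                pos[i] = target
            elif draws[t, 2, i] < p_transit:
                j = occupied[target]
                occupied[(x, y)] = j
                occupied[target] = i
                pos[j] = (x, y)
                pos[i] = target
        for i in range(n):
            traj[t, i, 0], traj[t, i, 1] = pos[i]
            nrec[t, i] = brute_force_count(
                occupied, pos[i][0], pos[i][1], width, height, r
            )
    return traj, nrec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_weight_stack():
    def make(n, seed=0):
        g = np.random.default_rng(seed)
        return g.uniform(-1.0, 1.0, size=(n, 11, 4))

    return make
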