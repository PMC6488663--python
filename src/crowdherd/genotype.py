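"""Behavioural genotypes: perception-to-direction neural networks.

Each agent's movement strategy is a two-layer fully connected network with
11 input nodes and 4 output nodes (one per direction), stored as an 11x4
weight table.  Outputs are plain weighted sums (linear activation: any
monotone activation is argmax-equivalent) and the movement direction is
the output with the largest value, ties broken uniformly at random.

Fixed input layout (indices into the percept vector and weight rows):

====  ===========================================================
slot  meaning
====  ===========================================================
0-3   occupancy state (0/1) of the adjacent cell to the N, S, E, W
4-7   neighbourhood size of the same four cells, divided by the
      window maximum (8.0 for radius 1) to normalise into [0, 1]
8     focal cell's neighbourhood size, same normalisation
9     uniform random value in [0, 1) — permits mixed strategies
10    constant bias 1.0
====  ===========================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .lattice import (
    DIRECTION_OFFSETS,
    AgentState,
    Direction,
    OccupancyLattice,
    neighbourhood_size,
)

__all__ = [
    "N_INPUTS",
    "N_OUTPUTS",
    "INPUT_NAMES",
    "Genotype",
    "Percept",
    "build_percept",
    "decide_direction",
    "random_genotype",
    "crossover_mutate",
    "genotype_weights",
    "stack_genotypes",
    "archive_to_json",
    "archive_from_json",
]

N_INPUTS = 11
N_OUTPUTS = 4

#: Human-readable input-node labels, index-aligned with the percept layout.
INPUT_NAMES = (
    "occupied_north",
    "occupied_south",
    "occupied_east",
    "occupied_west",
    "neigh_north",
    "neigh_south",
    "neigh_east",
    "neigh_west",
    "neigh_focal",
    "noise",
    "bias",
)

#: Index of the uniform-noise input node.
NOISE_SLOT = 9


@dataclass(frozen=True)
class Genotype:
    """An 11x4 weight table; ``weights[I, O]`` links input I to output O."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (N_INPUTS, N_OUTPUTS):
            raise ValueError(f"weight table must be {N_INPUTS}x{N_OUTPUTS}")
        if not np.all(np.isfinite(w)):
            raise ValueError("genotype weights must all be finite")
        object.__setattr__(self, "weights", w)

    def labelled(self) -> dict[str, dict[str, float]]:
        """Weight table keyed by input and direction names (inspection aid)."""
        return {
            INPUT_NAMES[i]: {
                d.name.lower(): float(self.weights[i, d.value])
                for d in Direction
            }
            for i in range(N_INPUTS)
        }


@dataclass(frozen=True)
class Percept:
    """The 11 locally perceived values feeding a genotype, fixed layout."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_INPUTS,):
            raise ValueError(f"percept must hold {N_INPUTS} values")
        object.__setattr__(self, "values", v)


def genotype_weights(g) -> np.ndarray:
    """Coerce a ``Genotype`` or bare array to a validated weight table."""
    if isinstance(g, Genotype):
        return g.weights
    return Genotype(np.asarray(g)).weights


def build_percept(
    lattice: OccupancyLattice,
    agent: AgentState,
    r: int = 1,
    rng: np.random.Generator | None = None,
    *,
    noise: float | None = None,
) -> Percept:
    """Assemble the 11-value percept for ``agent`` on ``lattice``.

    Neighbourhood sizes are divided by the window maximum ``(2r+1)² - 1``
    (8.0 for radius 1).  Note the querying agent itself occupies a real
    cell, so it is counted in the windows of its adjacent cells.  ``noise``
    may supply the pre-drawn uniform value for slot 9; otherwise one is
    drawn from ``rng``.
    """
    if noise is None:
        if rng is None:
            raise ValueError("build_percept needs a noise value or rng")
        noise = float(rng.random())
    window_max = (2 * r + 1) ** 2 - 1
    v = np.empty(N_INPUTS, dtype=np.float64)
    for d in Direction:
        dx, dy = DIRECTION_OFFSETS[d]
        tx, ty = lattice.wrap(agent.x + dx, agent.y + dy)
        v[d.value] = 0.0 if lattice.is_vacant(tx, ty) else 1.0
        v[4 + d.value] = neighbourhood_size(lattice, (tx, ty), r) / window_max
    v[8] = neighbourhood_size(lattice, agent.cell, r) / window_max
    v[9] = noise
    v[10] = 1.0
    return Percept(v)


def decide_direction(
    genotype,
    percept,
    rng: np.random.Generator | None = None,
    *,
    tie_u: float | None = None,
) -> Direction:
    """Direction whose output node (weighted input sum) is largest.

    Ties are broken uniformly at random — relevant for degenerate weight
    tables such as the all-zero genotype, where every output ties at 0.
    ``tie_u`` may supply the pre-drawn uniform for the tie-break.
    """
    w = genotype_weights(genotype)
    p = percept.values if isinstance(percept, Percept) else np.asarray(percept)
    out = p @ w
    if not np.all(np.isfinite(out)):
        raise ValueError("corrupt genotype: non-finite network output")
    best = out.max()
    tied = np.flatnonzero(out == best)
    if len(tied) == 1:
        return Direction(int(tied[0]))
    if tie_u is None:
        if rng is None:
            raise ValueError("tied outputs need a random source")
        tie_u = float(rng.random())
    return Direction(int(tied[int(tie_u * len(tied))]))


def random_genotype(rng: np.random.Generator, scale: float = 0.1) -> Genotype:
    """Initial-generation genotype: 44 weights i.i.d. uniform on
    ``[-scale, scale)``.

    The initial spread is a free model parameter (the evolved weight
    magnitudes are an emergent quantity, not an initialisation
    constraint); the default spans the unit interval on both sides.
    """
    if scale <= 0:
        raise ValueError("initial weight scale must be positive")
    return Genotype(rng.uniform(-scale, scale, size=(N_INPUTS, N_OUTPUTS)))


def crossover_mutate(
    parent_a,
    parent_b,
    mutation_variance: float,
    rng: np.random.Generator,
) -> Genotype:
    """Offspring genotype: uniform crossover plus Gaussian mutation.

    Each of the 44 weights is copied from one parent chosen independently
    with probability 1/2, then perturbed by an independent Gaussian draw
    with the given variance (the reference rate is variance 0.0005, i.e.
    standard deviation ~0.0224).  ``mutation_variance = 0`` yields pure
    crossover.  Consumes one uniform block then one normal block from
    ``rng``, in that order.
    """
    if mutation_variance < 0:
        raise ValueError("mutation variance must be >= 0")
    wa = genotype_weights(parent_a)
    wb = genotype_weights(parent_b)
    mask = rng.random((N_INPUTS, N_OUTPUTS)) < 0.5
    child = np.where(mask, wa, wb)
    if mutation_variance > 0:
        child = child + rng.normal(
            0.0, np.sqrt(mutation_variance), size=(N_INPUTS, N_OUTPUTS)
        )
    return Genotype(child)


def stack_genotypes(genotypes) -> np.ndarray:
    """Stack a genotype sequence into an ``(n, 11, 4)`` float64 array."""
    return np.stack([genotype_weights(g) for g in genotypes]).astype(np.float64)


def archive_to_json(generation: int, genotypes) -> str:
    """Serialise a population's genotypes (agent id + 44 weights each).

    Weights are written in the documented input-major order (11 rows of 4,
    N/S/E/W output columns); the round trip is bit-exact.
    """
    stacked = stack_genotypes(genotypes)
    doc = {
        "generation": int(generation),
        "input_names": list(INPUT_NAMES),
        "output_names": [d.name.lower() for d in Direction],
        "agents": [
            {"id": i, "weights": stacked[i].tolist()}
            for i in range(stacked.shape[0])
        ],
    }
    return json.dumps(doc)


def archive_from_json(text: str) -> tuple[int, np.ndarray]:
    """Inverse of :func:`archive_to_json`; returns (generation, weights)."""
    doc = json.loads(text)
    agents = sorted(doc["agents"], key=lambda rec: rec["id"])
    weights = np.array([rec["weights"] for rec in agents], dtype=np.float64)
    return int(doc["generation"]), weights
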