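"""Torus occupancy lattice and the crowding-constrained movement rule.

The spatial substrate of the model is a wrapped-around square lattice in
which every cell is either vacant or holds exactly one prey agent (the
cell is the projected body area / territory of the animal).  Movement is
restricted to the four adjacent cells and is blocked when the target is
occupied — unless the squeeze-through variant is enabled, in which case
the mover exchanges cells with the occupant with probability ``p_transit``.

Coordinate convention (documented, used everywhere): ``x`` is the column,
``y`` is the row, both 0-based; north is ``y - 1``, south ``y + 1``, east
``x + 1``, west ``x - 1``; both axes wrap (torus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "Direction",
    "MoveOutcome",
    "OccupancyLattice",
    "AgentState",
    "neighbourhood_size",
    "place_agents",
    "attempt_move",
    "step",
    "DIRECTION_OFFSETS",
]

VACANT = -1


class Direction(IntEnum):
    """One of the four movement targets, in the fixed N, S, E, W order.

    The integer values index genotype output columns and percept slots;
    the order is a global convention and must never be permuted.
    """

    NORTH = 0
    SOUTH = 1
    EAST = 2
    WEST = 3

    @property
    def offset(self) -> tuple[int, int]:
        """Unit lattice offset ``(dx, dy)`` for this direction."""
        return DIRECTION_OFFSETS[self]


#: (dx, dy) unit offsets, indexable by Direction.
DIRECTION_OFFSETS: dict[Direction, tuple[int, int]] = {
    Direction.NORTH: (0, -1),
    Direction.SOUTH: (0, 1),
    Direction.EAST: (1, 0),
    Direction.WEST: (-1, 0),
}


class MoveOutcome(Enum):
    """Result of a single movement attempt."""

    MOVED = "moved"
    BLOCKED = "blocked"
    SWAPPED = "swapped"


class OccupancyLattice:
    """A torus grid of cells, each vacant or holding exactly one agent id.

    Parameters
    ----------
    width, height:
        Cell counts along x (columns) and y (rows).

    Notes
    -----
    The occupancy map is stored as an ``(height, width)`` int32 array with
    ``-1`` marking vacancy, so it can be handed to the compiled simulation
    kernel without copying.
    """

    def __init__(self, width: int, height: int):
        if width < 1 or height < 1:
            raise ValueError("lattice dimensions must be positive")
        self.width = int(width)
        self.height = int(height)
        self.grid = np.full((self.height, self.width), VACANT, dtype=np.int32)

    # -- basic queries -------------------------------------------------

    def wrap(self, x: int, y: int) -> tuple[int, int]:
        """Map arbitrary integer coordinates onto the torus."""
        return x % self.width, y % self.height

    def occupant(self, x: int, y: int) -> int | None:
        """Agent id at cell ``(x, y)``, or ``None`` if vacant."""
        self._check_cell(x, y)
        a = int(self.grid[y, x])
        return None if a == VACANT else a

    def is_vacant(self, x: int, y: int) -> bool:
        self._check_cell(x, y)
        return self.grid[y, x] == VACANT

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.grid != VACANT))

    def occupied_cells(self) -> list[tuple[int, int, int]]:
        """All ``(agent_id, x, y)`` triples, sorted by agent id."""
        ys, xs = np.nonzero(self.grid != VACANT)
        triples = [(int(self.grid[y, x]), int(x), int(y)) for x, y in zip(xs, ys)]
        return sorted(triples)

    # -- mutation ------------------------------------------------------

    def place(self, agent_id: int, x: int, y: int) -> None:
        self._check_cell(x, y)
        if self.grid[y, x] != VACANT:
            raise ValueError(f"cell ({x}, {y}) already occupied")
        self.grid[y, x] = agent_id

    def remove(self, x: int, y: int) -> int:
        self._check_cell(x, y)
        a = int(self.grid[y, x])
        if a == VACANT:
            raise ValueError(f"cell ({x}, {y}) is vacant")
        self.grid[y, x] = VACANT
        return a

    def _check_cell(self, x: int, y: int) -> None:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValueError(
                f"cell ({x}, {y}) outside {self.width}x{self.height} lattice"
            )

    # -- serialisation -------------------------------------------------

    def to_json(self) -> str:
        """Serialise dimensions and occupied cells to a JSON document."""
        doc = {
            "width": self.width,
            "height": self.height,
            "agents": [
                {"id": a, "x": x, "y": y} for a, x, y in self.occupied_cells()
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "OccupancyLattice":
        doc = json.loads(text)
        lat = cls(doc["width"], doc["height"])
        for rec in doc["agents"]:
            lat.place(int(rec["id"]), int(rec["x"]), int(rec["y"]))
        return lat

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OccupancyLattice({self.width}x{self.height}, "
            f"{self.n_occupied} occupied)"
        )


@dataclass
class AgentState:
    """A prey agent: identity, current cell and per-generation accumulators.

    ``neighbour_sum`` accumulates the settled Moore-neighbourhood size once
    per time step; ``move_count`` counts time steps whose settled position
    differs from the step's starting position.  Both are zeroed at the start
    of every generation.
    """

    id: int
    x: int
    y: int
    neighbour_sum: float = 0.0
    move_count: int = 0
    steps_recorded: int = 0

    @property
    def cell(self) -> tuple[int, int]:
        return self.x, self.y


def neighbourhood_size(
    lattice: OccupancyLattice, cell: tuple[int, int], r: int = 1
) -> int:
    """Number of occupied cells in the Moore neighbourhood of ``cell``.

    The neighbourhood domain is the ``(2r+1)² - 1`` cells around the focal
    cell, diagonals included, excluding the focal cell itself; wrapping is
    applied on both axes.  This is the limited domain of danger used as the
    exposure measure: for radius 1 the count ranges over 0..8.
    """
    x, y = cell
    lattice._check_cell(x, y)
    if r < 1:
        raise ValueError("neighbourhood radius must be >= 1")
    count = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx == 0 and dy == 0:
                continue
            xx, yy = lattice.wrap(x + dx, y + dy)
            if lattice.grid[yy, xx] != VACANT:
                count += 1
    return count


def place_agents(
    lattice: OccupancyLattice, n: int, rng: np.random.Generator
) -> list[AgentState]:
    """Place ``n`` agents on distinct uniformly random cells.

    Emulates the loose pre-predation spread of a prey population at the
    start of a generation.  Consumes exactly one ``rng.choice`` draw.
    """
    capacity = lattice.width * lattice.height
    if n > capacity:
        raise ValueError(f"cannot place {n} agents on {capacity} cells")
    flat = rng.choice(capacity, size=n, replace=False)
    agents = []
    for i, f in enumerate(flat):
        y, x = divmod(int(f), lattice.width)
        lattice.place(i, x, y)
        agents.append(AgentState(id=i, x=x, y=y))
    return agents


def attempt_move(
    lattice: OccupancyLattice,
    agent: AgentState,
    direction: Direction,
    p_transit: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    u: float | None = None,
    agents: Sequence[AgentState] | None = None,
) -> MoveOutcome:
    """Try to move ``agent`` one cell in ``direction`` under crowding.

    If the target cell is vacant the agent relocates.  If it is occupied,
    the agent squeezes through with probability ``p_transit`` by atomically
    exchanging cells with the occupant (the displaced agent keeps its own
    later turn within the step); otherwise the agent stays put.

    Parameters
    ----------
    u:
        Optional pre-drawn uniform variate for the squeeze test; when
        omitted one is drawn from ``rng`` only if the target is occupied
        and ``p_transit > 0``.
    agents:
        When given (indexed by agent id), the displaced occupant's
        recorded position is updated on a swap.
    """
    if not 0.0 <= p_transit <= 1.0:
        raise ValueError("p_transit must lie in [0, 1]")
    dx, dy = direction.offset
    tx, ty = lattice.wrap(agent.x + dx, agent.y + dy)
    target = lattice.grid[ty, tx]
    if target == VACANT:
        lattice.grid[agent.y, agent.x] = VACANT
        lattice.grid[ty, tx] = agent.id
        agent.x, agent.y = tx, ty
        return MoveOutcome.MOVED
    if p_transit > 0.0:
        if u is None:
            if rng is None:
                raise ValueError("p_transit > 0 requires a random source")
            u = float(rng.random())
        if u < p_transit:
            lattice.grid[agent.y, agent.x] = int(target)
            lattice.grid[ty, tx] = agent.id
            if agents is not None:
                other = agents[int(target)]
                other.x, other.y = agent.x, agent.y
            agent.x, agent.y = tx, ty
            return MoveOutcome.SWAPPED
    return MoveOutcome.BLOCKED


def step(
    lattice: OccupancyLattice,
    agents: Sequence[AgentState],
    genotypes: Sequence["np.ndarray | object"],
    rng: np.random.Generator,
    *,
    r: int = 1,
    p_transit: float = 0.0,
    draws: np.ndarray | None = None,
    outcomes: list | None = None,
) -> np.ndarray:
    """Advance the lattice by one time step of asynchronous sequential moves.

    Every agent acts exactly once, in a fresh uniformly random order each
    step, and each decision reads the lattice state current at its turn.
    After all agents have acted, each agent's settled neighbourhood size is
    recorded into its accumulators and returned.

    Random-draw layout (the documented fixed sequence, shared with the
    compiled kernel): one ``(4, n)`` uniform block per step — row 0 order
    keys (ascending argsort gives the turn order), row 1 the noise input
    node, row 2 the squeeze test, row 3 the argmax tie-break — indexed by
    agent id and consumed unconditionally.  ``draws`` may supply this block
    directly; otherwise it is drawn from ``rng``.  When ``outcomes`` is a
    list, one ``(agent_id, MoveOutcome)`` pair per turn is appended to it.

    Returns
    -------
    numpy.ndarray
        Settled neighbourhood size per agent (indexed by agent id).
    """
    from .genotype import build_percept, decide_direction, genotype_weights

    n = len(agents)
    if draws is None:
        draws = rng.random((4, n))
    order = np.argsort(draws[0], kind="stable")
    start = [(a.x, a.y) for a in agents]
    for idx in order:
        agent = agents[idx]
        percept = build_percept(
            lattice, agent, r=r, noise=float(draws[1, agent.id])
        )
        w = genotype_weights(genotypes[agent.id])
        direction = decide_direction(
            w, percept, tie_u=float(draws[3, agent.id])
        )
        outcome = attempt_move(
            lattice,
            agent,
            direction,
            p_transit,
            u=float(draws[2, agent.id]),
            agents=agents,
        )
        if outcomes is not None:
            outcomes.append((agent.id, outcome))
    settled = np.empty(n, dtype=np.int64)
    for agent in agents:
        nsize = neighbourhood_size(lattice, agent.cell, r)
        settled[agent.id] = nsize
        agent.neighbour_sum += nsize
        agent.steps_recorded += 1
        if (agent.x, agent.y) != start[agent.id]:
            agent.move_count += 1
    return settled
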