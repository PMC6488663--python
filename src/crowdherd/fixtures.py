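"""Deterministic hand-built fixtures for tests and demonstrations.

Each fixture is a small lattice and/or hand-set genotype written as plain
JSON, with any expected counts computed by an embedded brute-force window
count that is independent of the simulation code paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .genotype import N_INPUTS, N_OUTPUTS, archive_to_json
from .lattice import Direction, OccupancyLattice

__all__ = ["FIXTURE_NAMES", "make_fixture", "always_north_weights", "all_zero_weights"]


def always_north_weights() -> np.ndarray:
    """Genotype whose only nonzero weight is bias -> north: a deterministic
    northbound walker."""
    w = np.zeros((N_INPUTS, N_OUTPUTS))
    w[10, Direction.NORTH] = 1.0
    return w


def all_zero_weights() -> np.ndarray:
    """All-zero genotype: every output ties at 0, so the direction is
    uniform random (the tie-break fixture)."""
    return np.zeros((N_INPUTS, N_OUTPUTS))


def _brute_force_counts(occupied: set[tuple[int, int]], width: int, height: int, r: int):
    """Independent window recount: for every cell, the number of occupied
    cells among all (2r+1)^2 - 1 window offsets, torus-wrapped."""
    counts = {}
    for y in range(height):
        for x in range(width):
            c = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dx == 0 and dy == 0:
                        continue
                    if ((x + dx) % width, (y + dy) % height) in occupied:
                        c += 1
            counts[(x, y)] = c
    return counts


def _lattice_json(width, height, cells):
    lat = OccupancyLattice(width, height)
    for i, (x, y) in enumerate(cells):
        lat.place(i, x, y)
    return lat.to_json()


#: Occupied cells of the 5x5 neighbourhood-test lattice (documented layout:
#: a 2x2 block, one diagonal contact and one isolated agent).
NEIGH_5X5_CELLS = [(1, 1), (2, 1), (1, 2), (2, 2), (3, 3), (0, 4)]

FIXTURE_NAMES = (
    "always_north",
    "all_zero",
    "block_2x2",
    "full_lattice",
    "neigh_5x5",
)


def make_fixture(name: str, outdir: str | Path) -> list[Path]:
    """Write the named fixture's files under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def write(fname: str, text: str) -> None:
        p = outdir / fname
        p.write_text(text)
        paths.append(p)

    if name == "always_north":
        write(
            "always_north.genotype.json",
            archive_to_json(0, [always_north_weights()]),
        )
    elif name == "all_zero":
        write(
            "all_zero.genotype.json",
            archive_to_json(0, [all_zero_weights()]),
        )
    elif name == "block_2x2":
        # four agents in a 2x2 block on an otherwise empty 6x6 lattice
        write(
            "block_2x2.lattice.json",
            _lattice_json(6, 6, [(2, 2), (3, 2), (2, 3), (3, 3)]),
        )
        write(
            "block_2x2.genotypes.json",
            archive_to_json(0, [always_north_weights()] * 4),
        )
    elif name == "full_lattice":
        # every cell of a 3x3 torus occupied: permanent full enclosure
        cells = [(x, y) for y in range(3) for x in range(3)]
        write("full_lattice.lattice.json", _lattice_json(3, 3, cells))
    elif name == "neigh_5x5":
        cells = NEIGH_5X5_CELLS
        counts = _brute_force_counts(set(cells), 5, 5, r=1)
        doc = {
            "width": 5,
            "height": 5,
            "occupied": [list(c) for c in cells],
            "radius": 1,
            "expected_counts": [
                {"x": x, "y": y, "count": counts[(x, y)]}
                for y in range(5)
                for x in range(5)
            ],
        }
        write("neigh_5x5.json", json.dumps(doc, indent=1))
    else:
        raise ValueError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        )
    return paths
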