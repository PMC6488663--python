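"""Phenotype and genotype analyses of evolved populations.

Phenotype level: the mobility score (per-step cell-change frequency) and
the conditional leave-probability profile — the probability that an agent
leaves its cell for a vacant neighbour, conditioned on how many Moore
neighbours it currently has.  The profile is the behavioural fingerprint
that separates the three evolved strategies (coward: never leave
neighbours; explorer: leave small groups; dodger: also abandon border
positions).

Genotype level: the pairwise strategy likelihood (one minus the mean
absolute link-weight difference over the 44 links) and the embedding of a
population against the three reference strategy topologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import genotype_weights, stack_genotypes

__all__ = [
    "ConditionalProfile",
    "StrategyReference",
    "STRATEGY_LABELS",
    "mobility_score",
    "conditional_profile",
    "genotype_likelihood",
    "strategy_reference",
    "strategy_embedding",
    "detect_change_points",
    "epoch_summary",
]

STRATEGY_LABELS = ("coward", "explorer", "dodger")


@dataclass
class ConditionalProfile:
    """Leave-probability profile by neighbourhood size.

    For each neighbourhood size ``n`` in 0..window max, ``occasions[n]``
    counts agent-steps that faced a transition with ``n`` settled
    neighbours and ``moves[n]`` those that left their cell.  Sizes never
    observed have probability NaN (undefined), not 0.
    """

    occasions: np.ndarray
    moves: np.ndarray

    def __post_init__(self):
        self.occasions = np.asarray(self.occasions, dtype=np.int64)
        self.moves = np.asarray(self.moves, dtype=np.int64)
        if self.occasions.shape != self.moves.shape:
            raise ValueError("occasions and moves must align")
        if np.any(self.moves > self.occasions) or np.any(self.moves < 0):
            raise ValueError("move counts must lie within occasion counts")

    @property
    def window_max(self) -> int:
        return len(self.occasions) - 1

    @property
    def probabilities(self) -> np.ndarray:
        occ = self.occasions.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(occ > 0, self.moves / occ, np.nan)

    @property
    def total_occasions(self) -> int:
        return int(self.occasions.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neighbourhood_size": np.arange(len(self.occasions)),
                "occasions": self.occasions,
                "moves_to_vacant": self.moves,
                "probability": self.probabilities,
            }
        )


@dataclass(frozen=True)
class StrategyReference:
    """A labelled reference topology: the element-wise mean weight table of
    an archived population at a strategy epoch of the same run."""

    label: str
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "weights", genotype_weights(self.weights)
        )


def mobility_score(trajectory) -> float:
    """Fraction of recorded transitions at which the cell changed.

    ``trajectory`` is the sequence of settled cells over T recorded time
    steps (T >= 2); the score averages the T - 1 step-to-step change
    indicators and lies in [0, 1].
    """
    cells = np.asarray(trajectory)
    if cells.ndim == 1:
        cells = cells[:, None]
    if cells.shape[0] < 2:
        raise ValueError("mobility score needs at least two recorded steps")
    changed = np.any(cells[1:] != cells[:-1], axis=1)
    return float(changed.mean())


def conditional_profile(
    trajectories,
    neighbour_sizes,
    *,
    window_max: int = 8,
) -> ConditionalProfile:
    """Conditional leave-probability profile from aligned settled records.

    Parameters
    ----------
    trajectories : (T, n, 2) or (T, n) array
        Settled positions per step (coordinate pairs, or any per-step cell
        labels that change iff the agent moved).
    neighbour_sizes : (T, n) int array
        Settled neighbourhood size per step, aligned with the positions.
    window_max:
        Largest possible neighbourhood size (8 for radius 1).

    An agent-step at time t contributes one occasion at its settled size
    ``neighbour_sizes[t]`` and one move when its settled position at t+1
    differs; t runs over the first T - 1 records.
    """
    traj = np.asarray(trajectories)
    sizes = np.asarray(neighbour_sizes)
    if traj.ndim == 2:
        traj = traj[:, :, None]
    if traj.shape[:2] != sizes.shape:
        raise ValueError("positions and neighbourhood sizes are misaligned")
    if sizes.shape[0] < 2:
        raise ValueError("profile needs at least two recorded steps")
    if sizes.min() < 0 or sizes.max() > window_max:
        raise ValueError("neighbourhood size outside [0, window max]")
    moved = np.any(traj[1:] != traj[:-1], axis=2)  # (T-1, n)
    cond = sizes[:-1]
    occasions = np.bincount(cond.ravel(), minlength=window_max + 1)
    moves = np.bincount(
        cond.ravel(), weights=moved.ravel(), minlength=window_max + 1
    ).astype(np.int64)
    return ConditionalProfile(occasions=occasions, moves=moves)


def genotype_likelihood(a, b) -> float:
    """Strategy likelihood between two genotypes.

    One minus the mean absolute difference of the 44 link weights:
    symmetric, at most 1, equal to 1 iff the genotypes are identical, and
    possibly negative for very distant genotypes (not clipped).
    """
    wa = genotype_weights(a)
    wb = genotype_weights(b)
    return float(1.0 - np.abs(wa - wb).mean())


def strategy_reference(label: str, population) -> StrategyReference:
    """Build a reference topology as the element-wise mean of an archived
    population's weight tables."""
    weights = (
        population
        if isinstance(population, np.ndarray) and population.ndim == 3
        else stack_genotypes(population)
    )
    return StrategyReference(label=label, weights=weights.mean(axis=0))


def strategy_embedding(
    population, references: list[StrategyReference] | tuple
) -> np.ndarray:
    """Per-agent likelihood coordinates against the reference strategies.

    Returns an ``(n, len(references))`` array whose columns follow the
    order of ``references`` (canonically coward, explorer, dodger); each
    entry is the strategy likelihood between the agent's genotype and the
    reference topology.
    """
    weights = (
        population
        if isinstance(population, np.ndarray) and population.ndim == 3
        else stack_genotypes(population)
    )
    refs = np.stack([r.weights for r in references])  # (k, 11, 4)
    diffs = np.abs(weights[:, None, :, :] - refs[None, :, :, :])
    return 1.0 - diffs.mean(axis=(2, 3))


def detect_change_points(
    series,
    *,
    window: int = 25,
    min_jump: float = 0.05,
) -> list[int]:
    """Locate the phase-transition boundaries of a per-generation series.

    A simple documented heuristic (the phase boundaries are an
    eyeball-level feature, not a precision target): the series is
    smoothed by comparing the mean of the ``window`` values before each
    index with the mean of the ``window`` values after it; indices where
    the absolute jump exceeds ``min_jump`` (on the scale of the series
    range) and that are local maxima of the jump within ``window`` are
    reported, in increasing order.
    """
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n < 2 * window + 1:
        return []
    span = float(s.max() - s.min())
    if span == 0.0:
        return []
    jumps = np.zeros(n)
    for i in range(window, n - window):
        jumps[i] = abs(s[i : i + window].mean() - s[i - window : i].mean())
    threshold = min_jump * span
    points: list[int] = []
    i = window
    while i < n - window:
        if jumps[i] >= threshold and jumps[i] == jumps[max(0, i - window) : i + window + 1].max():
            points.append(i)
            i += window
        else:
            i += 1
    return points


def epoch_summary(
    records,
    *,
    epochs=(0, 80, 200, 1000),
    change_point_window: int = 25,
) -> pd.DataFrame:
    """Tabulate population means at the requested epoch generations and
    flag detected phase boundaries on the mobility series.

    ``records`` is a sequence of per-generation records (anything with
    ``generation``, ``mean_neighbour_score`` and ``mean_mobility_score``).
    The returned frame has one row per requested epoch present in the
    records plus one row per detected change point (``kind`` column).
    """
    by_gen = {r.generation: r for r in records}
    gens = sorted(by_gen)
    mob = np.array([by_gen[g].mean_mobility_score for g in gens])
    rows = []
    for e in epochs:
        if e in by_gen:
            r = by_gen[e]
            rows.append(
                {
                    "generation": e,
                    "kind": "epoch",
                    "mean_neighbour_score": r.mean_neighbour_score,
                    "mean_mobility_score": r.mean_mobility_score,
                }
            )
    for idx in detect_change_points(mob, window=change_point_window):
        g = gens[idx]
        r = by_gen[g]
        rows.append(
            {
                "generation": g,
                "kind": "change_point",
                "mean_neighbour_score": r.mean_neighbour_score,
                "mean_mobility_score": r.mean_mobility_score,
            }
        )
    return pd.DataFrame(
        rows, columns=["generation", "kind", "mean_neighbour_score", "mean_mobility_score"]
    )
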