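"""The generational loop: interaction, exposure scoring, truncation selection.

A run consists of ``generations`` reproductive cycles.  In each cycle the
population is scattered at random over the lattice, interacts for
``steps`` asynchronous time steps, and is then scored: an agent's
neighbourhood score is its mean settled Moore-neighbourhood occupancy per
time step (the selfish-herd fitness proxy — exposed agents have few
neighbours), and its mobility score is the fraction of step-to-step
transitions at which it changed cell.  The ``kill_fraction`` of agents
with the lowest neighbourhood scores is removed ("predated") and replaced
by offspring of uniformly chosen survivor pairs via uniform crossover and
Gaussian weight mutation.  Survivor genotypes pass to the next generation
unmodified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from ._kernel import run_generation_kernel
from .genotype import Genotype, crossover_mutate, random_genotype, stack_genotypes
from .lattice import AgentState, OccupancyLattice, place_agents, step

__all__ = [
    "SimConfig",
    "GenerationRecord",
    "GenerationOutput",
    "SelectionResult",
    "EvolutionResult",
    "neighbourhood_score",
    "run_generation",
    "select_and_reproduce",
    "run_evolution",
    "records_to_frame",
    "EPOCH_GENERATIONS",
]

#: Representative strategy epochs (initial / coward / explorer / dodger);
#: genotype archives are always kept at these generations when reached.
EPOCH_GENERATIONS = (0, 80, 200, 1000)


@dataclass(frozen=True)
class SimConfig:
    """All run parameters.  Defaults are the reference study conditions:

    200 agents on a 120x120 torus, 2,000 time steps per generation,
    3,000 generations, Moore radius 1, 5% truncation per generation,
    mutation variance 0.0005, full crowding (``p_transit = 0``).

    ``init_weight_scale`` is the half-width of the uniform initial weight
    distribution.  Behaviour is invariant to a global weight scale (argmax
    readout), so this parameter effectively sets how large the fixed
    Gaussian mutation step is relative to the starting weights; the
    default keeps early genotypes plastic enough for the strategy
    succession to unfold (see the methods note).
    """

    width: int = 120
    height: int = 120
    n_agents: int = 200
    steps: int = 2000
    generations: int = 3000
    radius: int = 1
    kill_fraction: float = 0.05
    mutation_variance: float = 0.0005
    p_transit: float = 0.0
    init_weight_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be positive")
        if min(self.width, self.height) < 2 * self.radius + 1:
            raise ValueError("lattice must span the neighbourhood window")
        if self.n_agents < 1 or self.n_agents > self.width * self.height:
            raise ValueError("population must fit on the lattice")
        if self.steps < 2 or self.generations < 1:
            raise ValueError("steps and generations must be positive (steps >= 2)")
        if self.radius < 1:
            raise ValueError("neighbourhood radius must be >= 1")
        if not 0.0 < self.kill_fraction < 1.0:
            raise ValueError("kill fraction must lie in (0, 1)")
        if self.mutation_variance < 0:
            raise ValueError("mutation variance must be >= 0")
        if not 0.0 <= self.p_transit <= 1.0:
            raise ValueError("p_transit must lie in [0, 1]")
        if self.init_weight_scale <= 0:
            raise ValueError("initial weight scale must be positive")

    @property
    def window_max(self) -> int:
        """Largest possible neighbourhood size, ``(2r+1)² - 1``."""
        return (2 * self.radius + 1) ** 2 - 1

    @property
    def kill_count(self) -> int:
        """Number of agents predated per generation, ``round(mu * N)``."""
        return int(np.rint(self.kill_fraction * self.n_agents))

    @classmethod
    def scaled(cls, **overrides) -> "SimConfig":
        """Desk-scale profile: full lattice and population, shorter runs
        (500 steps/generation, 1,500 generations)."""
        base = dict(steps=500, generations=1500)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def with_(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)


@dataclass
class GenerationRecord:
    """Per-generation population statistics.

    ``occasions[n]`` / ``moves[n]`` tally, over all agents and all
    step-to-step transitions in the generation, how often an agent whose
    settled neighbourhood size was ``n`` faced the next step, and how
    often it left its cell — their ratio is the conditional leave
    probability profile.
    """

    generation: int
    neighbour_scores: np.ndarray
    mobility_scores: np.ndarray
    occasions: np.ndarray
    moves: np.ndarray
    killed_ids: np.ndarray | None = None
    survivor_ids: np.ndarray | None = None

    @property
    def mean_neighbour_score(self) -> float:
        return float(self.neighbour_scores.mean())

    @property
    def mean_mobility_score(self) -> float:
        return float(self.mobility_scores.mean())

    @property
    def var_neighbour_score(self) -> float:
        return float(self.neighbour_scores.var())

    @property
    def var_mobility_score(self) -> float:
        return float(self.mobility_scores.var())

    @property
    def leave_probabilities(self) -> np.ndarray:
        """Conditional leave probability per neighbourhood size; NaN where
        the size was never observed."""
        occ = self.occasions.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(occ > 0, self.moves / occ, np.nan)


@dataclass
class GenerationOutput:
    """Raw result of one generation's interaction phase."""

    record: GenerationRecord
    final_positions: np.ndarray  # (n, 2) settled (x, y)
    trajectories: np.ndarray | None = None  # (T, n, 2)
    neighbour_sizes: np.ndarray | None = None  # (T, n)


def neighbourhood_score(agent: AgentState, steps: int | None = None) -> float:
    """Mean settled neighbourhood size per recorded time step.

    This is the exposure/fitness proxy: the average over the generation of
    the number of occupied Moore-window cells around the agent, in
    [0, window max] (0..8 for radius 1).
    """
    n = agent.steps_recorded if steps is None else steps
    if n is None or n < 1:
        raise ValueError("neighbourhood score undefined without recorded steps")
    return agent.neighbour_sum / n


def run_generation(
    config: SimConfig,
    genotypes,
    rng: np.random.Generator,
    *,
    generation: int = 0,
    initial_positions: np.ndarray | None = None,
    use_kernel: bool = True,
    collect: bool = False,
) -> GenerationOutput:
    """Run one generation's interaction phase and score the population.

    The population is placed uniformly at random without overlap (or at
    ``initial_positions``, an ``(n, 2)`` array of (x, y) cells), then
    advanced through ``config.steps`` asynchronous time steps.  Random
    draws are consumed in the documented fixed order: one placement draw
    (when placing randomly), then a single ``(T, 4, n)`` uniform block.
    The compiled kernel and the pure-Python path (``use_kernel=False``)
    consume the identical stream and produce identical trajectories.

    With ``collect=True`` the settled per-step positions and
    neighbourhood sizes are returned for trajectory-level analyses.
    """
    n = config.n_agents
    weights = genotypes if isinstance(genotypes, np.ndarray) else stack_genotypes(genotypes)
    if weights.shape != (n, 11, 4):
        raise ValueError(f"need {n} genotypes of shape 11x4")

    lattice = OccupancyLattice(config.width, config.height)
    if initial_positions is None:
        agents = place_agents(lattice, n, rng)
    else:
        pos = np.asarray(initial_positions, dtype=np.int64)
        if pos.shape != (n, 2):
            raise ValueError("initial_positions must be (n, 2)")
        agents = []
        for i in range(n):
            lattice.place(i, int(pos[i, 0]), int(pos[i, 1]))
            agents.append(AgentState(id=i, x=int(pos[i, 0]), y=int(pos[i, 1])))

    T = config.steps
    draws = rng.random((T, 4, n))
    wmax = config.window_max

    if use_kernel:
        posx = np.array([a.x for a in agents], dtype=np.int64)
        posy = np.array([a.y for a in agents], dtype=np.int64)
        neighbour_sum = np.zeros(n, dtype=np.float64)
        transitions = np.zeros(n, dtype=np.int64)
        occasions = np.zeros(wmax + 1, dtype=np.int64)
        moves = np.zeros(wmax + 1, dtype=np.int64)
        traj = np.empty((T, n, 2), dtype=np.int64)
        nrec = np.empty((T, n), dtype=np.int64)
        status = run_generation_kernel(
            lattice.grid,
            posx,
            posy,
            np.ascontiguousarray(weights, dtype=np.float64),
            float(config.p_transit),
            config.radius,
            draws,
            neighbour_sum,
            transitions,
            occasions,
            moves,
            traj,
            nrec,
            False,
        )
        assert status == 0
        final_positions = np.stack([posx, posy], axis=1)
        mobility = transitions / (T - 1)
    else:
        genos = [Genotype(weights[i]) for i in range(n)]
        traj = np.empty((T, n, 2), dtype=np.int64)
        nrec = np.empty((T, n), dtype=np.int64)
        for t in range(T):
            settled = step(
                lattice,
                agents,
                genos,
                rng,
                r=config.radius,
                p_transit=config.p_transit,
                draws=draws[t],
            )
            nrec[t] = settled
            for a in agents:
                traj[t, a.id, 0] = a.x
                traj[t, a.id, 1] = a.y
        neighbour_sum = nrec.sum(axis=0).astype(np.float64)
        changed = np.any(traj[1:] != traj[:-1], axis=2)  # (T-1, n)
        mobility = changed.mean(axis=0)
        prof = _metrics.conditional_profile(traj, nrec, window_max=wmax)
        occasions, moves = prof.occasions, prof.moves
        final_positions = traj[-1].copy()

    record = GenerationRecord(
        generation=generation,
        neighbour_scores=neighbour_sum / T,
        mobility_scores=np.asarray(mobility, dtype=np.float64),
        occasions=np.asarray(occasions),
        moves=np.asarray(moves),
    )
    return GenerationOutput(
        record=record,
        final_positions=final_positions,
        trajectories=traj if collect else None,
        neighbour_sizes=nrec if collect else None,
    )


@dataclass
class SelectionResult:
    next_genotypes: np.ndarray  # (n, 11, 4)
    killed_ids: np.ndarray
    survivor_ids: np.ndarray


def select_and_reproduce(
    genotypes,
    scores: np.ndarray,
    kill_fraction: float,
    rng: np.random.Generator,
    *,
    mutation_variance: float = 0.0005,
) -> SelectionResult:
    """Truncation selection: predate the most exposed, refill from survivors.

    The ``round(kill_fraction * n)`` agents with the lowest neighbourhood
    scores are removed (ties at the cutoff broken uniformly at random — in
    particular, with all scores identical the killed set is a uniform
    random subset).  Each vacancy is refilled by an offspring of two
    distinct survivors drawn uniformly without replacement, produced by
    uniform crossover plus Gaussian mutation.  Survivors keep their ids
    and their genotypes unmodified.
    """
    weights = genotypes if isinstance(genotypes, np.ndarray) else stack_genotypes(genotypes)
    n = weights.shape[0]
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (n,):
        raise ValueError("scores must align with genotypes")
    if not 0.0 < kill_fraction < 1.0:
        raise ValueError("kill fraction must lie in (0, 1)")
    k = int(np.rint(kill_fraction * n))
    if k == 0:
        return SelectionResult(
            next_genotypes=weights.copy(),
            killed_ids=np.empty(0, dtype=np.int64),
            survivor_ids=np.arange(n, dtype=np.int64),
        )
    tiebreak = rng.random(n)
    order = np.lexsort((tiebreak, scores))
    killed = np.sort(order[:k])
    survivors = np.sort(order[k:])
    nxt = weights.copy()
    for slot in killed:
        pa, pb = rng.choice(survivors, size=2, replace=False)
        child = crossover_mutate(
            weights[pa], weights[pb], mutation_variance, rng
        )
        nxt[slot] = child.weights
    return SelectionResult(
        next_genotypes=nxt, killed_ids=killed, survivor_ids=survivors
    )


@dataclass
class EvolutionResult:
    """Everything a completed (or checkpoint-resumed) run produced."""

    config: SimConfig
    records: list[GenerationRecord]
    archives: dict[int, np.ndarray]
    final_genotypes: np.ndarray

    def metrics_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records: Sequence[GenerationRecord]) -> pd.DataFrame:
    """Tabulate per-generation population statistics.

    Columns: generation, mean/var of the neighbour and mobility scores,
    and the conditional leave probability per neighbourhood size
    (``p_move_n0`` .. ``p_move_n<window max>``; NaN when unobserved).
    """
    if not records:
        return pd.DataFrame()
    wmax = len(records[0].occasions) - 1
    rows = []
    for rec in records:
        row = {
            "generation": rec.generation,
            "mean_neighbour_score": rec.mean_neighbour_score,
            "mean_mobility_score": rec.mean_mobility_score,
            "var_neighbour_score": rec.var_neighbour_score,
            "var_mobility_score": rec.var_mobility_score,
        }
        probs = rec.leave_probabilities
        for nsize in range(wmax + 1):
            row[f"p_move_n{nsize}"] = probs[nsize]
        rows.append(row)
    return pd.DataFrame(rows)


def _rng_from_state(state: dict) -> np.random.Generator:
    bg = np.random.PCG64()
    bg.state = state
    return np.random.Generator(bg)


def run_evolution(
    config: SimConfig,
    *,
    archive_every: int = 20,
    epoch_generations: Sequence[int] = EPOCH_GENERATIONS,
    on_generation: Callable[[GenerationRecord], None] | None = None,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 100,
    resume_from: str | Path | None = None,
    use_kernel: bool = True,
) -> EvolutionResult:
    """Execute a full evolutionary run.

    Genotypes are drawn uniformly at random in the first generation, then
    carried through interaction, scoring and truncation selection for
    ``config.generations`` cycles.  Positions are re-randomised and
    accumulators zeroed every generation; only genotypes persist.  A
    genotype archive (a copy of the acting population's weight tables) is
    kept every ``archive_every`` generations and at the strategy epoch
    generations.  Runs are bit-reproducible: the same config and seed
    yield identical records, archives and checkpoints.

    ``checkpoint_path`` enables periodic JSON checkpoints (generation,
    genotypes, RNG state); ``resume_from`` continues a run from such a
    checkpoint, reproducing the uninterrupted run's remaining generations
    exactly.
    """
    if resume_from is not None:
        doc = json.loads(Path(resume_from).read_text())
        if doc["config"] != config.to_dict():
            raise ValueError("checkpoint config does not match")
        start = int(doc["generation"])
        weights = np.array(doc["genotypes"], dtype=np.float64)
        rng = _rng_from_state(_decode_rng_state(doc["rng_state"]))
    else:
        start = 0
        rng = np.random.default_rng(config.seed)
        weights = np.stack(
            [
                random_genotype(rng, config.init_weight_scale).weights
                for _ in range(config.n_agents)
            ]
        )

    records: list[GenerationRecord] = []
    archives: dict[int, np.ndarray] = {}
    for g in range(start, config.generations):
        if g in epoch_generations or (archive_every and g % archive_every == 0):
            archives[g] = weights.copy()
        if checkpoint_path is not None and g > start and g % checkpoint_every == 0:
            _write_checkpoint(checkpoint_path, config, g, weights, rng)
        out = run_generation(
            config, weights, rng, generation=g, use_kernel=use_kernel
        )
        rec = out.record
        sel = select_and_reproduce(
            weights,
            rec.neighbour_scores,
            config.kill_fraction,
            rng,
            mutation_variance=config.mutation_variance,
        )
        rec.killed_ids = sel.killed_ids
        rec.survivor_ids = sel.survivor_ids
        weights = sel.next_genotypes
        records.append(rec)
        if on_generation is not None:
            on_generation(rec)
    return EvolutionResult(
        config=config,
        records=records,
        archives=archives,
        final_genotypes=weights,
    )


def _encode_rng_state(rng: np.random.Generator) -> dict:
    st = rng.bit_generator.state
    return {
        "bit_generator": st["bit_generator"],
        "state": str(st["state"]["state"]),
        "inc": str(st["state"]["inc"]),
        "has_uint32": st["has_uint32"],
        "uinteger": st["uinteger"],
    }


def _decode_rng_state(doc: dict) -> dict:
    return {
        "bit_generator": doc["bit_generator"],
        "state": {"state": int(doc["state"]), "inc": int(doc["inc"])},
        "has_uint32": doc["has_uint32"],
        "uinteger": doc["uinteger"],
    }


def _write_checkpoint(path, config, generation, weights, rng) -> None:
    doc = {
        "config": config.to_dict(),
        "generation": int(generation),
        "genotypes": weights.tolist(),
        "rng_state": _encode_rng_state(rng),
    }
    Path(path).write_text(json.dumps(doc))
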