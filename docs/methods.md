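# Methods

## The model

`crowdherd` simulates the evolution of movement strategies in a selfish
herd whose members physically exclude one another.  The world is a
wrapped-around (torus) square lattice, by default 120 × 120 cells; each
cell is vacant or holds exactly one of N = 200 prey agents.  A cell is
the projected body area or territory of an animal, so crowding is
modelled by forbidding two agents from sharing a cell.

**Interaction.**  A generation consists of T time steps.  At each step
every agent acts exactly once, in a fresh uniformly random order, and
each decision reads the lattice as it stands at that agent's turn
(asynchronous sequential updating).  An agent perceives, for each of its
four adjacent cells (north, south, east, west): the occupancy state
(0/1) and the cell's Moore-neighbourhood size (occupied cells among the
8 surrounding cells, divided by 8 to normalise); plus its own cell's
normalised neighbourhood size, a uniform random value in [0, 1) (so
mixed strategies can evolve), and a constant bias of 1 — eleven inputs
in all.  Its genotype, an 11 × 4 weight table, maps these linearly to
four output values; the agent attempts to move one cell in the direction
of the largest output (ties broken uniformly at random; the readout is
argmax, so any monotone activation would be equivalent and linear
outputs are the minimal choice).  If the target cell is vacant the agent
relocates; if occupied, the agent stays put — unless the squeeze-through
variant is active, in which case it exchanges cells with the occupant
with probability `p_transit` (the displaced agent keeps its own later
turn in the same step; there are no cascading pushes).  Note there is no
explicit "stay" action: remaining in place is achieved by targeting an
occupied cell.

**Scores.**  After all agents have acted in a step, each agent's settled
neighbourhood size is recorded.  Over a generation this yields, per
agent: the *neighbourhood score* S^N (mean settled Moore occupancy per
step, the exposure/fitness proxy, in [0, 8] for radius 1) and the
*mobility score* S^M (fraction of step-to-step transitions at which the
settled cell changed, in [0, 1]).  Because T settled records define only
T − 1 transitions, S^M averages T − 1 indicators; the transition from
the random initial placement into the first settled record is excluded.
The behavioural fingerprint of a population is the *conditional leave
profile*: for each neighbourhood size n, the probability that an agent
with n settled neighbours at one step has changed cell by the next.
Sizes never observed are reported as undefined (NaN), not zero.  On
constructed configurations the boundary values are exact: an agent alone
on the lattice leaves with probability 1 (all targets vacant), and a
fully enclosed agent under full crowding leaves with probability 0.

**Selection.**  At the end of a generation the round(μN) agents with the
lowest neighbourhood scores are removed ("predated"), ties at the cutoff
broken uniformly at random; μ = 0.05 by default.  Each vacancy is filled
by an offspring of two distinct survivors drawn uniformly without
replacement: every weight is copied from one parent with probability 1/2
(uniform crossover) and then perturbed by an independent Gaussian draw
with variance 0.0005 (sd ≈ 0.022).  Survivor genotypes pass unchanged.
Positions are re-randomised and accumulators zeroed every generation;
only genotypes persist.  Truncation selection and global random mating
deliberately exclude kin- or group-selection effects.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| `width`, `height` | 120 × 120 | lattice cells (torus) |
| `n_agents` | 200 | population size (constant) |
| `steps` (T) | 2000 | movement rounds per generation |
| `generations` (G) | 3000 | reproductive cycles per run |
| `radius` (r) | 1 | Moore-neighbourhood radius; window max = (2r+1)²−1 |
| `kill_fraction` (μ) | 0.05 | predated fraction per generation |
| `mutation_variance` | 0.0005 | per-weight Gaussian mutation variance |
| `p_transit` | 0.0 | squeeze-through probability (0 = full blocking) |
| `init_weight_scale` | 0.1 | half-width of uniform initial weights |
| `seed` | 0 | PCG64 seed; runs are bit-reproducible |

`SimConfig.scaled()` is the desk-scale profile used by the test suite
and the acceptance script: the full lattice and population with T = 500
and G = 1500, sized so a run completes in roughly a minute and a half on
one core.

**Initial weight scale.**  The argmax readout makes behaviour invariant
to a global rescaling of a genotype, so the initial half-width does not
change what initial populations *do* — it sets how large the fixed
mutation step (sd ≈ 0.022) is relative to the starting weights, i.e.
how plastic early genotypes are.  With half-width 1.0 mutation moves
weights by ~2% per event and the population stays locked in the first
evolved strategy for well over a thousand generations; with the default
0.1 the coward-to-explorer succession unfolds within a couple of
thousand full-scale generations, and the mean absolute weight grows
emergently toward ~0.25 as selection fixes structure.  The half-width
is exposed as a configuration option.

As an analytic aside on the mutation rate: with variance 0.0005, the
probability that at least one of the 44 links of an offspring receives a
perturbation larger than 0.07 (10% of a typical evolved weight magnitude
of 0.7) is 44 · 2(1 − Φ(0.07/0.0224)) ≈ 0.078.

## What a run produces

Per generation: population means and variances of both scores, the
conditional leave profile, and the killed/survivor id sets (CSV export,
one row per generation).  Genotype archives (all 200 weight tables) are
kept on a configurable cadence and always at the strategy epoch
generations 0 / 80 / 200 / 1000, from which *reference topologies*
(element-wise mean weight tables, per-run since evolved weight signs are
run-specific) and the likelihood embedding are built: the likelihood
between two genotypes is 1 minus the mean absolute difference of their
44 weights — symmetric, 1 iff identical, possibly negative for very
distant genotypes (not clipped).  Phase boundaries on the per-generation
series are flagged by a simple documented heuristic (largest smoothed
jumps of the mean mobility series exceeding 5% of its range); the
boundaries are an eyeball-level descriptive aid, not a calibrated
estimator.

## Reproducibility and numerics

One PCG64 generator per run drives every stochastic element in a fixed
documented order: initial genotype draw; then per generation, the
placement draw followed by a single `(T, 4, N)` uniform block (per step:
order keys — their argsort is the turn order — noise inputs, squeeze
tests, tie-breaks, indexed by agent id and consumed unconditionally);
then the selection draws (cutoff tie-break keys, parent choices,
crossover masks, mutation perturbations).  The compiled (numba) inner
loop and the pure-Python reference path consume the identical stream and
are asserted trajectory-identical in the tests; an independent
brute-force re-simulation oracle provides a second, shared-code-free
check.  Checkpoints (generation, genotypes, RNG state) allow byte-exact
resumption.  Floating-point comparisons in the argmax are exact; with
continuous weights ties occur only on degenerate (e.g. all-zero)
genotypes, where the uniform tie-break applies.

## Simulated versus real herds — and versus the full-scale campaign

All data in this package are generated by the simulator itself under
the study conditions above; nothing is fitted to field data.  The model
abstracts predation into a per-generation fitness rule (no predator
agents), bodies into single cells, movement into four-neighbour lattice
hops, and perception into a two-cell horizon, so passing tests support
claims about the model's dynamics, not quantitative claims about any
animal system.

What the simulator demonstrably reproduces, under the default
full-scale conditions (T = 2000), is the first two stages of the
strategy succession and the squeeze-through contrast.  Under full
crowding, a verification run showed the coward phase (mean S^N ≈ 2.3,
leave probabilities near 0) holding from roughly generation 40 to 900,
then the explorer transition: by generation ~1300 the population
reached a stationary-herd state with mean S^N ≈ 4.5 and
P(leave | 1 neighbour) ≈ 0.93 while P(leave | 3+) stayed near 0, and
the mean absolute weight grew emergently from 0.05 to ≈ 0.25.  The
third stage — border agents also abandoning 3-5-neighbour positions,
dissolving the stationary herds into moving aggregates with mean
S^N ≈ 2 — did not appear within 3000 generations in our full-scale
runs; whether it requires longer runs, other seeds, or details of the
model this implementation resolves differently is an open question and
the main known gap between this simulator's dynamics and the behaviour
this model class is reported to show.  With unhindered transit
(p_transit = 1) the generation-0 population is genuinely dispersed
(swaps prevent the deadlocks described below), and evolution builds
cohesive herds whose mean S^N climbed to ≈ 3.9 by generation 1400 and
was still rising.

The desk-scale profile (T = 500, G = 1500) preserves the lattice,
population, and selection intensity but shortens both time horizons,
and this changes what is reachable.  First, the succession is slower
per generation (shorter generations give noisier selection): within
1500 desk-scale generations the runs we measured remained in the frozen
coward-like state, ending with mean S^N ≈ 1.8 under full crowding and
≈ 2.0 with unhindered transit.  Second, aggregation within a generation
is time-limited: from random scatter at this density, even deliberately
engineered herding strategies cannot push the population mean
neighbourhood score much beyond ≈ 2.5 within 500 steps (≈ 3.7 within
2000), so herd-level scores are structurally out of range of the short
profile regardless of genotype.  The acceptance script reports what the
scaled runs actually produce; the full-scale study conditions remain
the package defaults.

## Known limitations

- With independently drawn weights the argmax readout makes most initial
  genotypes near-deterministic marchers; under full crowding, colliding
  marchers deadlock, so generation-0 populations build up frozen strings
  and clusters (mean S^N ≈ 1.4 over a full-length generation) rather
  than staying mostly solitary.  This is intrinsic to the
  network-plus-argmax design and independent of the initial weight
  scale (a global rescaling changes no decision); it disappears when
  p_transit > 0, where swaps resolve deadlocks.
- Under the squeeze-through variant the mobility score and leave profile
  count settled position changes, which includes being displaced by a
  swap; "moving to a vacant cell" and "changing cell" are no longer the
  same event when `p_transit` > 0, and the package uses the
  position-change definition throughout.
- The kill count round(μN) is exact only when μN is representable; ties
  at the truncation cutoff are randomised rather than jointly killed.
- The change-point heuristic is descriptive; do not use it as a
  statistical test of phase structure.
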