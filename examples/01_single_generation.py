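"""One generation of crowded interaction, inspected in detail.

Builds a small population of random genotypes, runs a single generation
of asynchronous movement under full crowding, and prints the two scores
that summarise each agent's behaviour: the neighbourhood score (mean
Moore-window occupancy per step — the exposure/fitness proxy) and the
mobility score (fraction of steps at which the agent changed cell).
"""

import numpy as np

from crowdherd import SimConfig, conditional_profile, run_generation
from crowdherd.genotype import random_genotype, stack_genotypes

config = SimConfig(width=40, height=40, n_agents=60, steps=300, generations=1,
                   p_transit=0.0, seed=7)
rng = np.random.default_rng(config.seed)
genotypes = stack_genotypes([random_genotype(rng) for _ in range(config.n_agents)])

out = run_generation(config, genotypes, rng, collect=True)
rec = out.record

print(f"population: {config.n_agents} agents, {config.width}x{config.height} torus, "
      f"{config.steps} steps")
print(f"mean neighbourhood score: {rec.mean_neighbour_score:.3f}  "
      "(average Moore neighbours per agent per step; 0 = everyone alone, 8 = max)")
print(f"mean mobility score:      {rec.mean_mobility_score:.3f}  "
      "(fraction of steps an agent changed cell)")

prof = conditional_profile(out.trajectories, out.neighbour_sizes)
print("\nconditional leave probability by current neighbour count")
print("(random genotypes = the unevolved null behaviour):")
for n, p in enumerate(prof.probabilities):
    if prof.occasions[n] > 0:
        print(f"  n={n}: P(leave) = {p:.3f}   ({prof.occasions[n]} occasions)")
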