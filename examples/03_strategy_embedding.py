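"""Genotype-level analysis: likelihood embedding against epoch references.

Runs a short evolutionary simulation, builds reference strategy
topologies (element-wise mean weight tables of the population at chosen
epoch generations), and embeds every archived population by its
likelihood to each reference — the likelihood between two genotypes is
one minus the mean absolute difference of their 44 link weights, so 1.0
means identical strategies.
"""

from crowdherd import (
    SimConfig,
    run_evolution,
    strategy_embedding,
    strategy_reference,
)

config = SimConfig(width=50, height=50, n_agents=60, steps=150, generations=90,
                   seed=5)
result = run_evolution(config, archive_every=10)

epochs = (0, 40, 80)
references = [
    strategy_reference(label, result.archives[g])
    for label, g in zip(("initial", "middle", "late"), epochs)
]

print("per-generation mean likelihood to each epoch reference:")
print("generation   L(initial)   L(middle)   L(late)")
for g in sorted(result.archives):
    emb = strategy_embedding(result.archives[g], references).mean(axis=0)
    print(f"{g:10d}   {emb[0]:10.4f}   {emb[1]:9.4f}   {emb[2]:7.4f}")
print("\nThe ordering flips as evolution proceeds: generation 0 is likeliest")
print("to the initial reference, the final generation to the late one — the")
print("population's weight tables drift away from the random start as one")
print("coherent cloud.  Over long runs that traverse the full strategy")
print("succession, the same embedding built from the canonical epoch")
print("archives (generations 80/200/1000) traces the coward -> explorer ->")
print("dodger trajectory.")
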