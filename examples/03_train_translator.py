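"""Train the conditional WGAN-GP translator on one small network.

The model learns to map subgraph adjacency matrices at a lower
connectivity level (N81-like) to the same subgraphs one level up
(N90-like). This is a deliberately small run so it finishes in about
a minute on one CPU; see the run configuration notes in docs/methods.md
for how the scaled-down profile relates to the full recipe.
"""

import numpy as np

from ganlink import (
    FixtureConfig, SamplerConfig, TrainingConfig, build_pairs,
    enumerate_subgraphs, generate_network, holdout_edge_split, train,
)
from ganlink.cgan import generate

net = generate_network(FixtureConfig(n_nodes=200, target_sparsity=0.03, n_blocks=4, seed=2))
split = holdout_edge_split(net, keep_fraction=0.9, seed=1)

specs = enumerate_subgraphs(split.retained, SamplerConfig(l=36, seed=0))
pairs = build_pairs(split.retained, net, specs)
print(f"{len(pairs)} training pairs from {split.retained.n_edges}-edge network")

config = TrainingConfig(
    epochs=8, batch_size=16, critic_steps=1, l1_weight=1000.0,
    learning_rate=2e-3, base_channels=8, seed=0,
)
generator = train(pairs, config, tracker=pairs[:16])

stats = generator.train_stats
print(f"critic/generator updates: {stats['critic_updates']}/{stats['generator_updates']}")
print(f"first generator loss:     {stats['generator_loss'][0]:.3f}")
print(f"last generator loss:      {stats['generator_loss'][-1]:.3f}")
print(f"validation MAE by epoch:  {[round(v['mae'], 4) for v in stats['validation']]}")

out = generate(generator, pairs[0].condition.matrix)
known = out[pairs[0].condition.matrix == 1]
absent = out[(pairs[0].target.matrix == 0) & (pairs[0].condition.matrix == 0)]
print(f"confidence at known edges:  {known.mean():.3f}")
print(f"confidence at absent pairs: {absent.mean():.3f}")
# A falling generator loss and a widening gap between known-edge and
# absent-pair confidences show the translator picking up the topology.
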