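"""Generate a synthetic PPI-like network and inspect its shape.

High-confidence interactomes are sparse (well under 1% of all possible
pairs), heavy-tailed in degree, and dominated by one giant component.
This script builds such a fixture and prints the properties that
matter for the downstream pipeline.
"""

import networkx as nx
import numpy as np

from ganlink import FixtureConfig, generate_network

config = FixtureConfig(
    n_nodes=1000,
    target_sparsity=0.005,
    model="scale_free",
    n_isolated_small_components=3,
    seed=7,
)
net = generate_network(config)

degrees = np.array([len(net.neighbors(n)) for n in net.nodes])
components = sorted(nx.connected_components(net.to_networkx()), key=len, reverse=True)

print(f"nodes:            {net.n_nodes}")
print(f"edges:            {net.n_edges}")
print(f"density:          {net.density():.4%}  (target {config.target_sparsity:.2%})")
print(f"max/mean degree:  {degrees.max()} / {degrees.mean():.1f}")
print(f"components:       {len(components)} (giant: {len(components[0])} nodes)")
print(f"small components: {[len(c) for c in components[1:]]}")
# The giant component carries nearly all nodes; the small components are
# below the subgraph limit l=36 and will be invisible to the sampler,
# exactly like the isolated modules of a real interactome.
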