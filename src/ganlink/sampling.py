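"""Fixed-size induced-subgraph extraction by a modified breadth-first search.

Starting from a node, whole BFS layers are appended while the running
node count (start node included) stays below the limit l; the first
layer that would reach or exceed l contributes exactly the missing
number of nodes, drawn uniformly at random.  Every emitted subgraph
therefore has exactly l nodes.  Start nodes whose connected component
holds fewer than l nodes (including isolated nodes) yield nothing.

Randomness for each start node comes from an independent stream derived
from the configured seed and a stable hash of the node identifier, so
results do not depend on enumeration order or dict iteration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .network_io import InteractionNetwork


@dataclass(frozen=True)
class SamplerConfig:
    """Node limit l (the subgraph side length) and the master seed."""

    l: int = 36
    seed: int = 0

    def __post_init__(self):
        if self.l < 2:
            raise ValueError(f"node limit l must be >= 2, got {self.l}")


@dataclass(frozen=True)
class SubgraphSpec:
    """An ordered list of exactly l nodes: the start node, the fully
    included BFS layers, then the randomly filled nodes from the
    overflow layer."""

    start: str
    nodes: tuple[str, ...]
    layer_sizes: tuple[int, ...]  # sizes of fully included neighbor layers
    n_filled: int  # nodes drawn at random from the overflow layer

    def __post_init__(self):
        if self.nodes[0] != self.start:
            raise ValueError("start node must be first in the node list")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("subgraph nodes must be distinct")
        if 1 + sum(self.layer_sizes) + self.n_filled != len(self.nodes):
            raise ValueError("layer accounting does not match node count")

    @property
    def l(self) -> int:
        return len(self.nodes)


def _node_stream(seed: int, node: str) -> np.random.Generator:
    digest = hashlib.blake2b(node.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(digest, "big")])
    )


def extract_subgraph(
    network: InteractionNetwork, start: str, config: SamplerConfig
) -> SubgraphSpec | None:
    """One fixed-size subgraph around ``start``, or None if its
    component is smaller than the limit."""
    if start not in network.nodes:
        raise KeyError(f"start node {start!r} not in network")
    l = config.l
    adj = network.adjacency()
    visited = {start}
    chosen: list[str] = [start]
    layer_sizes: list[int] = []
    frontier = [start]
    while len(chosen) < l:
        nxt: set[str] = set()
        for u in frontier:
            nxt.update(adj[u])
        nxt -= visited
        if not nxt:
            return None  # component exhausted below the limit
        layer = sorted(nxt)
        if len(chosen) + len(layer) < l:
            chosen.extend(layer)
            layer_sizes.append(len(layer))
            visited.update(layer)
            frontier = layer
        else:
            n_fill = l - len(chosen)
            rng = _node_stream(config.seed, start)
            picks = rng.choice(len(layer), size=n_fill, replace=False)
            chosen.extend(sorted(layer[int(i)] for i in picks))
            return SubgraphSpec(
                start=start,
                nodes=tuple(chosen),
                layer_sizes=tuple(layer_sizes),
                n_filled=n_fill,
            )
    # len(chosen) == l can only happen via the fill branch, but guard anyway
    return SubgraphSpec(
        start=start, nodes=tuple(chosen), layer_sizes=tuple(layer_sizes), n_filled=0
    )


def enumerate_subgraphs(
    network: InteractionNetwork, config: SamplerConfig
) -> list[SubgraphSpec]:
    """One spec per eligible start node, in sorted node order."""
    specs = []
    for node in sorted(network.nodes):
        spec = extract_subgraph(network, node, config)
        if spec is not None:
            specs.append(spec)
    return specs


def write_subgraphs(specs, path) -> None:
    """CSV with one row per spec: start node then the l member IDs."""
    with open(path, "w") as fh:
        for spec in specs:
            fh.write(",".join((spec.start,) + spec.nodes) + "\n")


def read_subgraphs(path) -> list[SubgraphSpec]:
    """Read specs written by :func:`write_subgraphs`.

    Layer bookkeeping is not stored on disk, so round-tripped specs
    carry all non-start nodes as a single layer.
    """
    specs = []
    with open(path) as fh:
        for line in fh:
            fields = line.strip().split(",")
            if not fields or fields == [""]:
                continue
            start, nodes = fields[0], tuple(fields[1:])
            specs.append(
                SubgraphSpec(
                    start=start,
                    nodes=nodes,
                    layer_sizes=(len(nodes) - 1,),
                    n_filled=0,
                )
            )
    return specs
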