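"""Subgraph adjacency matrices and condition/target training pairs.

A subgraph spec fixes a node ordering; indexing the same node group at
two connectivity levels yields the condition (sparser) and target
(denser) binary matrices the translation model trains on.  The
condition builder is pluggable so alternative input encodings (e.g.
node-embedding matrices) can be slotted in without touching the rest
of the pipeline; only the adjacency builder is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .network_io import InteractionNetwork, canon_pair
from .sampling import SubgraphSpec


@dataclass(frozen=True)
class SubgraphAdjacency:
    """l-by-l binary adjacency of a spec's nodes in spec order;
    symmetric with a zero diagonal."""

    spec: SubgraphSpec
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        l = self.spec.l
        if m.shape != (l, l):
            raise ValueError(f"matrix shape {m.shape} != ({l}, {l})")


@dataclass(frozen=True)
class TrainingPair:
    """Condition (lower connectivity) and target (higher connectivity)
    matrices over one spec; the target dominates the condition
    elementwise."""

    spec: SubgraphSpec
    condition: SubgraphAdjacency
    target: SubgraphAdjacency

    def __post_init__(self):
        if np.any(self.condition.matrix > self.target.matrix):
            raise ValueError("condition matrix exceeds target matrix somewhere")

    @property
    def heldout_matrix(self) -> np.ndarray:
        """0/1 matrix marking the held-out edges internal to the spec."""
        return self.target.matrix - self.condition.matrix


def subgraph_adjacency(
    network: InteractionNetwork, spec: SubgraphSpec
) -> SubgraphAdjacency:
    """Induced adjacency matrix of the spec's nodes, in spec order."""
    missing = [n for n in spec.nodes if n not in network.nodes]
    if missing:
        raise KeyError(f"spec nodes missing from network: {missing[:3]}")
    l = spec.l
    m = np.zeros((l, l), dtype=np.float32)
    edges = network.edges
    for i, j in combinations(range(l), 2):
        if canon_pair(spec.nodes[i], spec.nodes[j]) in edges:
            m[i, j] = m[j, i] = 1.0
    return SubgraphAdjacency(spec=spec, matrix=m)


ConditionBuilder = Callable[[InteractionNetwork, SubgraphSpec], SubgraphAdjacency]


def build_pairs(
    lower: InteractionNetwork,
    higher: InteractionNetwork,
    specs: Sequence[SubgraphSpec],
    condition_builder: ConditionBuilder = subgraph_adjacency,
) -> list[TrainingPair]:
    """Pair every spec's lower-level matrix with the matrix of the same
    node group at the higher level."""
    if not lower.edges <= higher.edges:
        raise ValueError("lower-level edges are not a subset of the higher level")
    pairs = []
    for spec in specs:
        cond = condition_builder(lower, spec)
        target = subgraph_adjacency(higher, spec)
        pairs.append(TrainingPair(spec=spec, condition=cond, target=target))
    return pairs


def stack_conditions(pairs: Sequence[TrainingPair]) -> np.ndarray:
    """(M, 1, l, l) float32 stack of condition matrices."""
    return np.stack([p.condition.matrix for p in pairs])[:, None, :, :]


def stack_targets(pairs: Sequence[TrainingPair]) -> np.ndarray:
    return np.stack([p.target.matrix for p in pairs])[:, None, :, :]
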