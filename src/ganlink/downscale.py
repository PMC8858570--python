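"""Connectivity-level hierarchy by randomized edge removal.

The full network (conventionally "N100") is downscaled twice: a k-fold
edge split keeps (k-1)/k of the edges per fold ("N90" at k = 10), and a
secondary holdout keeps a further fraction of those ("N81" at 0.9).
The removed edges simulate the not-yet-discovered part of the
interactome; nodes are never removed, so components that shrink below
the subgraph limit are simply filtered later by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, train_test_split

from .network_io import InteractionNetwork, Pair


@dataclass
class FoldSplit:
    """One fold of an edge holdout: the retained network plus the
    removed (held-out) edges, which together partition the parent's
    edge set."""

    fold_index: int
    retained: InteractionNetwork
    removed_edges: set[Pair]


def _canonical_edge_array(network: InteractionNetwork) -> list[Pair]:
    # sorted before shuffling so splits do not depend on input file order
    return sorted(network.edges)


def kfold_edge_split(
    network: InteractionNetwork, k: int = 10, seed: int = 0
) -> list[FoldSplit]:
    """Split the edge set into k folds; each fold's retained network
    keeps the other k-1 parts (90% of edges at k = 10).

    The removed sets partition the edge set.  Node sets are preserved.
    Deterministic for a fixed seed.
    """
    if network.n_edges < k:
        raise ValueError(f"need at least k={k} edges, have {network.n_edges}")
    edges = _canonical_edge_array(network)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(splitter.split(edges)):
        removed = {edges[j] for j in test_idx}
        retained = InteractionNetwork(
            nodes=set(network.nodes),
            edges={edges[j] for j in train_idx},
            name=f"{network.name or 'net'} fold {i}",
        )
        folds.append(FoldSplit(fold_index=i, retained=retained, removed_edges=removed))
    return folds


def holdout_edge_split(
    network: InteractionNetwork, keep_fraction: float = 0.9, seed: int = 0
) -> FoldSplit:
    """Remove a uniform random sample of edges, keeping
    floor(keep_fraction * |E| + 0.5) of them (round half up)."""
    if not 0.0 < keep_fraction < 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1), got {keep_fraction}")
    if network.n_edges < 2:
        raise ValueError("need at least 2 edges for a holdout split")
    edges = _canonical_edge_array(network)
    n_keep = int(np.floor(keep_fraction * len(edges) + 0.5))
    n_keep = min(max(n_keep, 1), len(edges) - 1)
    kept, removed = train_test_split(
        edges, train_size=n_keep, shuffle=True, random_state=seed
    )
    retained = InteractionNetwork(
        nodes=set(network.nodes),
        edges=set(kept),
        name=f"{network.name or 'net'} holdout",
    )
    return FoldSplit(fold_index=0, retained=retained, removed_edges=set(removed))
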