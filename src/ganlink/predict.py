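"""Aggregate per-subgraph confidence matrices into a ranked candidate list.

A node pair may co-occur in many subgraphs and each l-by-l confidence
matrix scores it twice (both orientations); the pair's confidence is
the maximum over all of these.  Pairs already linked in the input
network are pruned.  Held-out links whose endpoints never co-occur in
any subgraph can receive no score at all; the coverage report accounts
for that blind spot separately instead of silently ignoring it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .network_io import InteractionNetwork, Pair, PredictionRecord, canon_pair
from .sampling import SubgraphSpec


@dataclass(frozen=True)
class CoverageReport:
    """How much of the network the subgraph sample can see."""

    node_coverage_input: float
    node_coverage_target: float
    unpredictable_fraction: float

    def __post_init__(self):
        for f in (
            self.node_coverage_input,
            self.node_coverage_target,
            self.unpredictable_fraction,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"coverage fraction {f} outside [0, 1]")


def aggregate_predictions(
    outputs: Iterable[tuple[SubgraphSpec, np.ndarray]],
    input_network: InteractionNetwork,
) -> list[PredictionRecord]:
    """Max-aggregate confidences over subgraphs, prune known links, rank.

    Candidates are all unordered pairs co-occurring in at least one
    subgraph.  Result is sorted by descending confidence, ties broken
    by lexicographic pair.
    """
    best: dict[Pair, float] = {}
    for spec, matrix in outputs:
        l = spec.l
        if matrix.shape != (l, l):
            raise ValueError(f"matrix shape {matrix.shape} != spec size ({l}, {l})")
        sym = np.maximum(matrix, matrix.T)
        nodes = spec.nodes
        for i, j in combinations(range(l), 2):
            pair = canon_pair(nodes[i], nodes[j])
            conf = float(sym[i, j])
            prev = best.get(pair)
            if prev is None or conf > prev:
                best[pair] = conf
    records = [
        PredictionRecord(pair=pair, confidence=min(max(conf, 0.0), 1.0))
        for pair, conf in best.items()
        if pair not in input_network.edges
    ]
    records.sort(key=lambda r: (-r.confidence, r.pair))
    return records


def coverage_stats(
    specs: Sequence[SubgraphSpec],
    input_network: InteractionNetwork,
    expected_links: set[Pair],
    target_network: InteractionNetwork | None = None,
) -> CoverageReport:
    """Node coverage of the subgraph sample and the share of expected
    links that cannot receive a score because their endpoints never
    co-occur in a subgraph."""
    overlap = expected_links & input_network.edges
    if overlap:
        raise ValueError(
            f"expected links must be disjoint from input edges; overlap {len(overlap)}"
        )
    covered: set[str] = set()
    for spec in specs:
        covered.update(spec.nodes)
    target = target_network or input_network
    cov_in = len(covered & input_network.nodes) / max(input_network.n_nodes, 1)
    cov_tgt = len(covered & target.nodes) / max(target.n_nodes, 1)
    if expected_links:
        co_occurring = set()
        for spec in specs:
            members = set(spec.nodes)
            for u, v in expected_links:
                if u in members and v in members:
                    co_occurring.add((u, v))
        unpredictable = (len(expected_links) - len(co_occurring)) / len(expected_links)
    else:
        unpredictable = 0.0
    return CoverageReport(
        node_coverage_input=cov_in,
        node_coverage_target=cov_tgt,
        unpredictable_fraction=unpredictable,
    )
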