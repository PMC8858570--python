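"""Canonical in-memory network representation and edge-list / prediction I/O.

Interactomes arrive as plain delimited edge lists (two ID columns, any
extra columns such as interaction scores are ignored).  Edges are
undirected, deduplicated and stored as lexicographically sorted pairs;
self-interactions are dropped on read and never predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canon_pair(a: str, b: str) -> Pair:
    """The unordered pair (a, b) in canonical (sorted) orientation."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionNetwork:
    """An undirected simple graph of protein identifiers.

    Nodes are opaque strings; edges are canonical unordered pairs.  The
    same object represents every connectivity level of the downscaling
    hierarchy (the full network and its edge-truncated versions).
    """

    nodes: set[str]
    edges: set[Pair]
    name: str = ""

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-pair {u!r} not allowed in edge set")
            if u > v:
                raise ValueError(f"edge {(u, v)!r} not in canonical orientation")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {(u, v)!r} has endpoint outside node set")
        self._adj: dict[str, set[str]] | None = None

    # -- graph views ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for u, v in self.edges:
                adj[u].add(v)
                adj[v].add(u)
            self._adj = adj
        return self._adj

    def neighbors(self, node: str) -> set[str]:
        return self.adjacency()[node]

    def has_edge(self, a: str, b: str) -> bool:
        return canon_pair(a, b) in self.edges

    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else 2.0 * self.n_edges / (n * (n - 1))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other):
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass(frozen=True, order=True)
class PredictionRecord:
    """One candidate interaction with its aggregated confidence."""

    pair: Pair
    confidence: float

    def __post_init__(self):
        a, b = self.pair
        if a == b:
            raise ValueError("prediction pair endpoints must be distinct")
        import math

        if not math.isfinite(self.confidence) or not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path: str | Path, delimiter: str = ",", skip_header: bool = False
) -> InteractionNetwork:
    """Read a two-column delimited edge list into a network.

    Extra columns (e.g. interaction scores) are ignored.  Reversed
    duplicates collapse to one undirected edge; self-pairs are dropped
    (their node is kept) and counted in a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    nodes: set[str] = set()
    edges: set[Pair] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if skip_header and lineno == 1:
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            nodes.update((a, b))
            if a == b:
                n_self += 1
                continue
            edges.add(canon_pair(a, b))
    if n_self:
        logger.info("dropped %d self-pair line(s) while reading %s", n_self, path)
    return InteractionNetwork(nodes=nodes, edges=edges, name=path.stem)


def write_edge_list(
    network: InteractionNetwork, path: str | Path, delimiter: str = ","
) -> None:
    """Write one line per edge, endpoints and lines in sorted order."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}{delimiter}{v}\n")


# ---------------------------------------------------------------------------
# prediction files

PREDICTION_HEADER = "node_a,node_b,confidence"


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write the ranked candidate list as CSV.

    The caller must supply records sorted by descending confidence with
    ties broken by lexicographic pair; violating that contract is an
    error rather than silently re-sorting.
    """
    records = list(records)
    for prev, cur in zip(records, records[1:]):
        if cur.confidence > prev.confidence or (
            cur.confidence == prev.confidence and cur.pair < prev.pair
        ):
            raise ValueError("prediction records are not sorted (confidence desc, pair asc)")
    with open(path, "w") as fh:
        fh.write(PREDICTION_HEADER + "\n")
        for rec in records:
            a, b = rec.pair
            fh.write(f"{a},{b},{rec.confidence:.6f}\n")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != PREDICTION_HEADER:
            raise ValueError(f"unexpected prediction header: {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b, conf = line.split(",")
            records.append(PredictionRecord(pair=canon_pair(a, b), confidence=float(conf)))
    return records
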