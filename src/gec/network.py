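"""Undirected, unweighted molecular networks.

The central object is :class:`Network`, a simple graph over string gene
identifiers.  Node order is fixed lexicographically so that every matrix
derived from a network (adjacency, graphlet adjacency, normalised forms)
has a reproducible row/column order regardless of input order.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["Network"]


class Network:
    """A simple undirected graph over string-labelled genes.

    Parameters
    ----------
    nodes:
        Iterable of node identifiers.  Nodes mentioned only in ``edges``
        are added automatically; listing a node here is how isolated
        nodes enter the network.
    edges:
        Iterable of 2-tuples of node identifiers.  Duplicate and
        reversed edges collapse to a single undirected edge.  Self-loops
        raise ``ValueError`` (use :func:`gec.io.read_network` for
        tolerant parsing of files that may contain them).
    """

    __slots__ = ("_nodes", "_index", "_adj", "_n_edges")

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        node_set = set(nodes)
        edge_set: set[frozenset[str]] = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            node_set.add(u)
            node_set.add(v)
            edge_set.add(frozenset((u, v)))
        self._nodes: tuple[str, ...] = tuple(sorted(node_set))
        self._index: dict[str, int] = {u: i for i, u in enumerate(self._nodes)}
        self._adj: dict[str, set[str]] = {u: set() for u in self._nodes}
        for e in edge_set:
            u, v = tuple(e)
            self._adj[u].add(v)
            self._adj[v].add(u)
        self._n_edges = len(edge_set)

    # -- basic protocol ------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Nodes in the deterministic (lexicographic) order."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._nodes == other._nodes and self._adj == other._adj

    def __hash__(self):  # pragma: no cover - mutability guard
        raise TypeError("Network is not hashable")

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def index(self, node: str) -> int:
        """Position of ``node`` in the deterministic node order."""
        return self._index[node]

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._adj[node])

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def edges(self) -> list[tuple[str, str]]:
        """All edges as sorted tuples, in deterministic order."""
        out = []
        for u in self._nodes:
            for v in self._adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    # -- derived structures --------------------------------------------

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """The induced subgraph on ``nodes`` (must all be present)."""
        keep = set(nodes)
        missing = keep - set(self._nodes)
        if missing:
            raise KeyError(f"nodes not in network: {sorted(missing)[:5]}")
        edges = [
            (u, v)
            for u in keep
            for v in self._adj[u]
            if v in keep and u < v
        ]
        return Network(keep, edges)

    def adjacency_matrix(self) -> sp.csr_array:
        """The 0/1 adjacency matrix in the deterministic node order."""
        rows, cols = [], []
        for u, v in self.edges():
            i, j = self._index[u], self._index[v]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows), dtype=np.int64)
        n = self.n_nodes
        return sp.csr_array((data, (rows, cols)), shape=(n, n))

    def adjacency_sets(self) -> list[set[int]]:
        """Neighbour sets in index space (used by the enumerators)."""
        return [
            {self._index[v] for v in self._adj[u]} for u in self._nodes
        ]

    def connected_components(self) -> list[set[str]]:
        seen: set[str] = set()
        comps: list[set[str]] = []
        for start in self._nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    def is_connected(self) -> bool:
        return self.n_nodes <= 1 or len(self.connected_components()) == 1

    # -- interop -------------------------------------------------------

    @classmethod
    def from_networkx(cls, graph) -> "Network":
        """Build from a ``networkx`` graph, stringifying node labels."""
        return cls(
            (str(u) for u in graph.nodes),
            ((str(u), str(v)) for u, v in graph.edges if u != v),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self.edges())
        return g
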