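"""Graphlets G0-G8 and graphlet adjacency matrices.

A *graphlet* is a small, connected, non-isomorphic, induced subgraph.
The nine graphlets on 2-4 nodes are, by convention:

====  =====  ==================================
id    nodes  shape
====  =====  ==================================
G0    2      single edge
G1    3      path
G2    3      triangle
G3    4      path
G4    4      star (claw)
G5    4      cycle
G6    4      triangle with a pendant edge (paw)
G7    4      4-clique minus one edge (diamond)
G8    4      4-clique
====  =====  ==================================

Two nodes u, v are *graphlet adjacent* with respect to Gi to the extent
that they simultaneously touch induced occurrences of Gi.  An occurrence
is a node *set* whose induced subgraph is isomorphic to Gi; it is counted
once per node set, not once per automorphism (on the 4-node fragment
a-b, b-c, b-e the pair (a, b) touches the 3-node path twice, via a-b-c
and a-b-e).  The graphlet adjacency matrix divides the raw pair counts
c_uv by the scaling constant theta = k(Gi) - 1, which makes every row sum
equal the node's graphlet degree (each occurrence containing u pairs it
with exactly k - 1 other nodes).  For G0 the matrix is exactly the
standard 0/1 adjacency matrix.

Enumeration uses ESU-style neighbourhood expansion of connected node
subsets, which visits every connected induced subset exactly once;
exhaustive enumeration over all C(n, k) subsets lives in the test suite
as an independent oracle.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import Network

__all__ = [
    "GRAPHLET_IDS",
    "graphlet_size",
    "classify_induced",
    "enumerate_connected_subsets",
    "enumerate_occurrences",
    "pair_count",
    "graphlet_degree",
    "graphlet_adjacency",
    "GraphletAdjacency",
]

GRAPHLET_IDS = tuple(range(9))

_SIZES = (2, 3, 3, 4, 4, 4, 4, 4, 4)


def graphlet_size(g: int) -> int:
    """Number of nodes k(Gi) of graphlet ``g``."""
    _check_graphlet(g)
    return _SIZES[g]


def _check_graphlet(g: int) -> None:
    if g not in GRAPHLET_IDS:
        raise ValueError(f"invalid graphlet id {g!r}; expected 0..8")


def classify_induced(n_nodes: int, n_edges: int, max_degree: int) -> int:
    """Graphlet id of a *connected* induced subgraph on 2-4 nodes.

    The (size, edge count, maximum degree) triple separates all nine
    graphlets: on 4 nodes, 3 edges is a path unless some node has degree
    3 (star), and 4 edges is a cycle unless some node has degree 3 (paw).
    """
    if n_nodes == 2:
        return 0
    if n_nodes == 3:
        return 1 if n_edges == 2 else 2
    if n_nodes == 4:
        if n_edges == 3:
            return 4 if max_degree == 3 else 3
        if n_edges == 4:
            return 6 if max_degree == 3 else 5
        if n_edges == 5:
            return 7
        return 8
    raise ValueError(f"graphlets are defined on 2-4 nodes, got {n_nodes}")


def _classify_subset(subset: tuple[int, ...], adj: list[set[int]]) -> int:
    degs = [len(adj[u] & set(subset)) for u in subset]
    return classify_induced(len(subset), sum(degs) // 2, max(degs))


def enumerate_connected_subsets(
    net: Network, k: int
) -> Iterator[tuple[int, ...]]:
    """Yield every connected induced node subset of size ``k`` once.

    Subsets are emitted as sorted tuples of node *indices* (positions in
    ``net.nodes``).  ESU recursion: grow from each root over extension
    sets restricted to indices above the root, adding only the exclusive
    neighbourhood of the newly adopted node, which guarantees each
    connected subset is generated exactly once.
    """
    if k < 1:
        raise ValueError("subset size must be positive")
    adj = net.adjacency_sets()
    n = net.n_nodes

    def extend(
        sub: list[int], ext: set[int], nbrs: set[int], root: int
    ) -> Iterator[tuple[int, ...]]:
        if len(sub) == k:
            yield tuple(sorted(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            # exclusive neighbourhood of w: new frontier nodes only
            excl = {u for u in adj[w] if u > root and u not in nbrs}
            excl.discard(w)
            yield from extend(
                sub + [w], ext | excl, nbrs | excl | {w}, root
            )

    for v in range(n):
        if k == 1:
            yield (v,)
            continue
        ext0 = {u for u in adj[v] if u > v}
        yield from extend([v], ext0, ext0 | {v}, v)


def enumerate_occurrences(net: Network, g: int) -> Iterator[frozenset[str]]:
    """Yield each induced occurrence of graphlet ``g`` as a node set.

    Every node subset whose induced subgraph is isomorphic to ``g`` is
    emitted exactly once; emission order is unspecified.
    """
    _check_graphlet(g)
    adj = net.adjacency_sets()
    nodes = net.nodes
    for subset in enumerate_connected_subsets(net, _SIZES[g]):
        if _classify_subset(subset, adj) == g:
            yield frozenset(nodes[i] for i in subset)


def pair_count(net: Network, g: int, u: str, v: str) -> int:
    """Number of occurrences of ``g`` containing both ``u`` and ``v``.

    The raw count c_uv before theta scaling; symmetric in (u, v).  The
    diagonal is undefined (the matrix puts 0 there), so ``u == v`` is
    rejected.
    """
    _check_graphlet(g)
    if u == v:
        raise ValueError("pair counts are defined for distinct nodes only")
    if u not in net or v not in net:
        raise KeyError(f"nodes {u!r}, {v!r} must both be in the network")
    count = 0
    for occ in enumerate_occurrences(net, g):
        if u in occ and v in occ:
            count += 1
    return count


def graphlet_degree(net: Network, g: int) -> np.ndarray:
    """Vector d^Gi: occurrences of ``g`` touching each node.

    Indexed by the deterministic node order.  For G0 this is the
    ordinary degree.
    """
    _check_graphlet(g)
    return graphlet_adjacency(net, g).degrees


@dataclass(frozen=True)
class GraphletAdjacency:
    """Graphlet adjacency matrix A_Gi = pair_counts / theta for one graphlet.

    Attributes
    ----------
    graphlet:
        Graphlet id 0-8.
    nodes:
        Row/column labels (the network's deterministic node order).
    pair_counts:
        Symmetric sparse integer matrix of raw co-occurrence counts
        c_uv, zero diagonal.
    theta:
        Scaling constant k(Gi) - 1.
    matrix:
        A_Gi = pair_counts / theta (float).  Row sums equal ``degrees``.
    degrees:
        Graphlet degree vector d^Gi (integer).
    """

    graphlet: int
    nodes: tuple[str, ...]
    pair_counts: sp.csr_array
    theta: int
    matrix: sp.csr_array
    degrees: np.ndarray

    @property
    def n_occurrences(self) -> int:
        k = _SIZES[self.graphlet]
        return int(self.degrees.sum()) // k

    def degree_of(self, node: str) -> int:
        return int(self.degrees[self.nodes.index(node)])


def graphlet_adjacency(net: Network, g: int) -> GraphletAdjacency:
    """Assemble the graphlet adjacency structure for graphlet ``g``.

    One ESU pass enumerates the connected subsets of size k(g); each
    occurrence of ``g`` increments the pair count of all C(k, 2) node
    pairs it contains and the graphlet degree of its k nodes.
    """
    _check_graphlet(g)
    k = _SIZES[g]
    theta = k - 1
    n = net.n_nodes
    adj = net.adjacency_sets()
    counts: dict[tuple[int, int], int] = {}
    degrees = np.zeros(n, dtype=np.int64)
    for subset in enumerate_connected_subsets(net, k):
        if _classify_subset(subset, adj) != g:
            continue
        for a_pos, i in enumerate(subset):
            degrees[i] += 1
            for j in subset[a_pos + 1:]:
                counts[(i, j)] = counts.get((i, j), 0) + 1
    if counts:
        ij = np.array(list(counts.keys()), dtype=np.int64)
        c = np.array(list(counts.values()), dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.concatenate([c, c])
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
        data = np.zeros(0, dtype=np.int64)
    pair_counts = sp.csr_array((data, (rows, cols)), shape=(n, n))
    matrix = pair_counts.astype(np.float64) / theta
    return GraphletAdjacency(
        graphlet=g,
        nodes=net.nodes,
        pair_counts=pair_counts,
        theta=theta,
        matrix=matrix,
        degrees=degrees,
    )
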