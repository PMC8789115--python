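"""Pathway gene sets and local/global pathway centrality.

A pathway is a gene set; its *pathway network* is the subgraph induced
on the genes that are present in the molecular network.  Centrality of
the pathway's genes can be computed two ways:

* **local** — build the graphlet adjacency of the pathway-induced
  subnetwork and take its leading eigenvector; the pathway is treated as
  an entity of its own, disentangled from the rest of the network;
* **global** — compute the graphlet eigencentrality of the full network
  once, then take the subvector on the pathway's genes (no
  renormalisation: only the within-pathway relative order is consumed
  downstream).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

from .centrality import (
    CentralityVector,
    GraphletSupportError,
    graphlet_eigencentrality,
)
from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "PathwayCentralityResult",
    "induce_pathway",
    "local_pathway_centrality",
    "global_pathway_centrality",
    "filter_pathways",
]


@dataclass
class PathwayCollection:
    """Mapping pathway-ID -> gene set, with a free-text provenance tag."""

    pathways: dict[str, frozenset[str]]
    provenance: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for pid, genes in self.pathways.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            clean[pid] = genes
        self.pathways = clean

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.pathways))

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.pathways[pid]

    def items(self) -> list[tuple[str, frozenset[str]]]:
        return [(pid, self.pathways[pid]) for pid in self]

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def multiplicity(self) -> dict[str, int]:
        """Number of pathways each annotated gene participates in."""
        mult: dict[str, int] = {}
        for genes in self.pathways.values():
            for g in genes:
                mult[g] = mult.get(g, 0) + 1
        return mult


@dataclass(frozen=True)
class PathwayCentralityResult:
    """Centrality scores for one (pathway, graphlet, mode) triple.

    ``scores`` covers exactly the pathway's genes present in the
    network.  ``degenerate`` marks pathways in which the graphlet has no
    occurrence (all-zero local scores): downstream evaluation reports
    them as NA rather than failing the batch.
    """

    pathway: str
    graphlet: int
    mode: str
    scores: Mapping[str, float]
    degenerate: bool = False


def induce_pathway(net: Network, genes: Iterable[str]) -> Network:
    """Induced subnetwork on the pathway genes present in ``net``.

    Genes absent from the network are dropped with a logged warning;
    an empty intersection is an error.
    """
    genes = set(genes)
    present = {g for g in genes if g in net}
    missing = genes - present
    if missing:
        logger.warning(
            "%d of %d pathway genes absent from the network (e.g. %s)",
            len(missing), len(genes), sorted(missing)[:3],
        )
    if not present:
        raise ValueError("no pathway gene is present in the network")
    return net.subgraph(present)


def local_pathway_centrality(
    net: Network,
    genes: Iterable[str],
    g: int,
    pathway: str = "",
) -> PathwayCentralityResult:
    """Graphlet eigencentrality computed inside the pathway subnetwork."""
    sub = induce_pathway(net, genes)
    try:
        vec = graphlet_eigencentrality(sub, g)
    except GraphletSupportError:
        logger.warning(
            "pathway %s: no occurrence of graphlet G%d; flagged degenerate",
            pathway or "<unnamed>", g,
        )
        return PathwayCentralityResult(
            pathway=pathway, graphlet=g, mode="local",
            scores={u: 0.0 for u in sub.nodes}, degenerate=True,
        )
    return PathwayCentralityResult(
        pathway=pathway, graphlet=g, mode="local",
        scores=vec.to_dict(), degenerate=False,
    )


def global_pathway_centrality(
    net: Network,
    genes: Iterable[str],
    g: int,
    cache: CentralityVector,
    pathway: str = "",
) -> PathwayCentralityResult:
    """Subvector of the full-network centrality on the pathway genes.

    ``cache`` must be the full-network graphlet eigencentrality for the
    same graphlet, computed once per (network, graphlet) pair.
    """
    if cache.graphlet != g:
        raise ValueError(
            f"cache holds graphlet G{cache.graphlet}, requested G{g}"
        )
    present = sorted(x for x in set(genes) if x in net)
    if not present:
        raise ValueError("no pathway gene is present in the network")
    return PathwayCentralityResult(
        pathway=pathway, graphlet=g, mode="global",
        scores=cache.restrict(present), degenerate=False,
    )


def filter_pathways(
    net: Network,
    collection: PathwayCollection,
    min_size: int = 10,
    max_size: int = 100,
) -> PathwayCollection:
    """Keep pathways that induce a connected subgraph of 10-100 genes.

    Size and connectivity are measured on the subgraph induced by the
    pathway genes present in the network (genes absent from the network
    are ignored); connectivity is plain (G0) connectivity.  The filter
    restricts each kept pathway's gene set to its in-network genes.
    """
    kept: dict[str, frozenset[str]] = {}
    for pid, genes in collection.items():
        present = frozenset(g for g in genes if g in net)
        if not (min_size <= len(present) <= max_size):
            continue
        if not net.subgraph(present).is_connected():
            continue
        kept[pid] = present
    if not kept:
        logger.warning("no pathway passed the size/connectivity filter")
    return PathwayCollection(
        pathways=kept,
        provenance=collection.provenance,
        descriptions={
            p: collection.descriptions.get(p, "") for p in kept
        },
    )
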