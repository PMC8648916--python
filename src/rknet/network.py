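"""Edge selection, signed network construction and walktrap modules.

Edges are chosen either by a hard q-value threshold or by taking the k
most significant pairs (the paper-style "top 500" rule); the sign of an
edge is the sign of its Z-statistic.  Modules are found with the walktrap
random-walk algorithm (walk length 20 by default) on the positive-edge
subgraph only; nodes connected to the rest of the network solely by
negative edges remain unassigned.  Module ids are relabelled in decreasing
order of size so "module 1" is always the largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .reboot import AssociationResult
from .tables import AbundanceTable, TaxonomyTable

__all__ = [
    "CooccurrenceNetwork",
    "select_edges",
    "build_network",
    "detect_modules",
    "module_taxonomy_concordance",
]


@dataclass
class CooccurrenceNetwork:
    """Signed co-occurrence graph with optional module labels.

    ``nodes`` maps otu_id -> attribute dict (``module`` may be None for
    unassigned nodes); ``edges`` maps a sorted (otu_a, otu_b) tuple to the
    edge's statistics (sign, similarity, z, p, q).
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has a missing endpoint")

    def positive_edges(self) -> list[tuple[str, str]]:
        return [pair for pair, e in self.edges.items() if e["sign"] == "+"]

    def negative_edges(self) -> list[tuple[str, str]]:
        return [pair for pair, e in self.edges.items() if e["sign"] == "-"]

    def modules(self) -> dict[str, object]:
        return {o: attrs.get("module") for o, attrs in self.nodes.items()}


def select_edges(
    results: list[AssociationResult],
    mode: str = "top_k",
    k: int = 500,
    q_max: float = 0.05,
) -> tuple[list[AssociationResult], float]:
    """Pick the edges of the network.

    ``top_k`` keeps the k smallest-q results (ties broken by larger |z|,
    then lexicographic pair); ``q_threshold`` keeps every result with
    ``q <= q_max``.  Returns the kept results and the effective q-value of
    the last included edge (NaN when nothing is kept).
    """
    if any(not np.isfinite(r.q) for r in results):
        raise ValueError("results contain non-finite q-values")
    if mode == "top_k":
        if k > len(results):
            warnings.warn(f"asked for top {k} edges but only {len(results)} "
                          "associations available; keeping all")
            k = len(results)
        ordered = sorted(results, key=lambda r: (r.q, -abs(r.z), r.otu_a, r.otu_b))
        kept = ordered[:k]
    elif mode == "q_threshold":
        kept = [r for r in results if r.q <= q_max]
    else:
        raise ValueError(f"unknown edge-selection mode {mode!r}")
    effective_q = max((r.q for r in kept), default=float("nan"))
    return kept, effective_q


def build_network(
    edges: list[AssociationResult],
    abundance: AbundanceTable | None = None,
    relative: AbundanceTable | None = None,
    taxonomy: TaxonomyTable | None = None,
    taxonomy_rank: str = "class",
) -> CooccurrenceNetwork:
    """Assemble the signed graph from selected associations.

    Mean abundances (absolute and/or relative, for logarithmic node
    sizing) and a taxonomy label are attached to nodes when the
    corresponding tables are given.
    """
    nodes: dict[str, dict] = {}

    def mean_of(table: AbundanceTable | None, otu: str) -> float | None:
        if table is None or otu not in table.otu_ids:
            return None
        return float(table.values[:, table.otu_ids.index(otu)].mean())

    edge_map: dict[tuple[str, str], dict] = {}
    for r in edges:
        pair = tuple(sorted((r.otu_a, r.otu_b)))
        for otu in pair:
            if otu not in nodes:
                nodes[otu] = {
                    "module": None,
                    "mean_abundance": mean_of(abundance, otu),
                    "mean_relative_abundance": mean_of(relative, otu),
                    "taxonomy": (taxonomy.labels.get(otu, {}).get(taxonomy_rank)
                                 if taxonomy is not None else None),
                }
        edge_map[pair] = {"sign": r.sign, "similarity": r.similarity,
                          "z": r.z, "p": r.p, "q": r.q}
    return CooccurrenceNetwork(nodes, edge_map)


def detect_modules(
    net: CooccurrenceNetwork, steps: int = 20, weighted: bool = False
) -> dict[str, int | None]:
    """Walktrap community detection on the positive-edge subgraph.

    The walk length is ``steps`` and the partition is cut at maximum
    modularity.  Negative edges play no part in the clustering; nodes that
    carry only negative edges are left unassigned (label ``None``).  With
    ``weighted=True`` the walk is biased by |z| edge weights.  Module ids
    are assigned in decreasing order of module size, starting at 1, and
    written back onto ``net``.
    """
    if not net.nodes:
        raise ValueError("network is empty")
    pos = net.positive_edges()
    if not pos:
        warnings.warn("no positive edges; all nodes left unassigned")
        for attrs in net.nodes.values():
            attrs["module"] = None
        return net.modules()
    pos_nodes = sorted({o for pair in pos for o in pair})
    index = {o: i for i, o in enumerate(pos_nodes)}
    g = ig.Graph(n=len(pos_nodes), edges=[(index[a], index[b]) for a, b in pos])
    weights = ([abs(net.edges[pair]["z"]) for pair in pos]) if weighted else None
    clustering = g.community_walktrap(weights=weights, steps=steps).as_clustering()
    membership = clustering.membership
    sizes = np.bincount(membership)
    order = np.argsort(-sizes, kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    for o, attrs in net.nodes.items():
        attrs["module"] = relabel[membership[index[o]]] if o in index else None
    return net.modules()


def module_taxonomy_concordance(
    partition: dict[str, object], taxonomy: TaxonomyTable, rank: str = "class"
) -> float:
    """Adjusted Rand index between module membership and taxonomy at a rank,
    over module-assigned OTUs that carry a label at that rank."""
    labels = taxonomy.rank_labels(rank)
    common = [o for o, m in partition.items() if m is not None and o in labels]
    if len(common) < 2:
        raise ValueError(f"fewer than 2 module-assigned OTUs labelled at rank {rank!r}")
    return float(adjusted_rand_score([labels[o] for o in common],
                                     [str(partition[o]) for o in common]))
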