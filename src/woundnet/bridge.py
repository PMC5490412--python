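"""Bridge-node detection and annotation-based ranking.

Bridge nodes sit between dense modules: they have few neighbors themselves
but carry much of the information flow across the network. They are scored by
*bridging centrality*

    BR(n) = RWBC(n) * BCoeff(n)

where RWBC is the random-walk (current-flow) betweenness centrality with edge
confidences as conductances, and the bridging coefficient

    BCoeff(n) = D(n)^-1 / sum_{v in N(n)} D(v)^-1

(with D the unweighted degree and N(n) the neighbor set) is large when a
low-degree node is surrounded by high-degree ones. Nodes above the 90th
percentile of BR are selected as bridges and then ranked by annotation
relevance: for each bridge the number of process-relevant KEGG pathways and
GO terms annotating it is counted, rescaled to [0, 1] by the per-category
maximum over the bridge set, and combined noisy-OR style:

    S_tot(b) = 1 - (1 - S_KEGG(b)) * (1 - S_GO(b)).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import AnnotationCatalog
from .errors import UsageError
from .network import WeightedNetwork

__all__ = [
    "BridgeScore",
    "bridging_coefficient",
    "random_walk_betweenness",
    "bridging_centrality",
    "select_bridge_nodes",
    "score_bridges",
    "write_bridge_scores",
]


@dataclass(frozen=True)
class BridgeScore:
    """Per-node bridging record; annotation fields are filled for bridges only."""

    node: str
    rwbc: float
    bcoeff: float
    br: float
    count_kegg: int = 0
    count_go: int = 0
    s_kegg: float = 0.0
    s_go: float = 0.0
    s_tot: float = 0.0
    rank: int | None = None


def bridging_coefficient(
    network: WeightedNetwork, node: str, weighted: bool = False
) -> float:
    """Inverse degree of ``node`` over the summed inverse degrees of its
    neighbors. Unweighted degrees by default; ``weighted=True`` substitutes
    weighted degrees. Isolated nodes (or nodes whose neighbors are all
    isolated, impossible in a simple graph) return 0 by convention.
    """
    graph = network.graph
    if node not in graph:
        raise ValueError(f"node {node!r} not in network")
    if weighted:
        deg = {u: sum(d["weight"] for d in graph.adj[u].values()) for u in graph}
    else:
        deg = dict(graph.degree())
    if deg[node] == 0:
        return 0.0
    denom = sum(1.0 / deg[v] for v in graph.adj[node] if deg[v] > 0)
    if denom == 0:
        return 0.0
    return (1.0 / deg[node]) / denom


def random_walk_betweenness(network: WeightedNetwork) -> dict[str, float]:
    """Current-flow betweenness with confidences as conductances.

    Computed independently on every connected component and normalized by the
    source-target pair count within the component; nodes in components of
    fewer than 3 nodes (where no node can ever be intermediate) score 0.
    """
    graph = network.graph
    result = {u: 0.0 for u in graph}
    for component in nx.connected_components(graph):
        if len(component) < 3:
            continue
        sub = graph.subgraph(component)
        result.update(
            nx.current_flow_betweenness_centrality(sub, normalized=True, weight="weight")
        )
    return result


def bridging_centrality(network: WeightedNetwork) -> list[BridgeScore]:
    """BR = RWBC x BCoeff for every node, sorted by node label."""
    rwbc = random_walk_betweenness(network)
    scores = []
    for node in sorted(network.graph.nodes):
        bc = bridging_coefficient(network, node)
        scores.append(
            BridgeScore(node=node, rwbc=rwbc[node], bcoeff=bc, br=rwbc[node] * bc)
        )
    return scores


def select_bridge_nodes(
    scores: Sequence[BridgeScore], percentile: float = 90.0
) -> list[BridgeScore]:
    """Scores whose BR strictly exceeds the given percentile of all BR values
    (linear-interpolation percentile, matching the hub-degree convention)."""
    if len(scores) < 2:
        raise UsageError("bridge selection needs at least 2 scored nodes")
    threshold = float(np.percentile([s.br for s in scores], percentile, method="linear"))
    return [s for s in scores if s.br > threshold]


def score_bridges(
    bridges: Sequence[BridgeScore],
    catalog: AnnotationCatalog,
    reference_kegg: Iterable[str],
    reference_go: Iterable[str],
) -> list[BridgeScore]:
    """Rank bridge nodes by process-relevant annotation counts.

    ``count_kegg``/``count_go`` count the reference terms annotating each
    bridge; the S scores divide by the per-category maximum over the bridge
    set (0 when the maximum is 0) and combine into
    S_tot = 1 - (1 - S_KEGG)(1 - S_GO). The returned list is sorted by
    descending S_tot, ties by descending BR then node label, with 1-based
    ranks filled in.
    """
    if not bridges:
        raise UsageError("bridge set is empty")
    ref_k = frozenset(reference_kegg)
    ref_g = frozenset(reference_go)
    kegg_terms = [t for t in catalog.terms if t.category == "KEGG" and t.term_id in ref_k]
    go_terms = [t for t in catalog.terms if t.category == "GO" and t.term_id in ref_g]
    counts = {
        b.node: (
            sum(b.node in t.genes for t in kegg_terms),
            sum(b.node in t.genes for t in go_terms),
        )
        for b in bridges
    }
    max_k = max(c[0] for c in counts.values())
    max_g = max(c[1] for c in counts.values())
    ranked = []
    for b in bridges:
        ck, cg = counts[b.node]
        s_k = ck / max_k if max_k else 0.0
        s_g = cg / max_g if max_g else 0.0
        ranked.append(
            replace(
                b,
                count_kegg=ck,
                count_go=cg,
                s_kegg=s_k,
                s_go=s_g,
                s_tot=1.0 - (1.0 - s_k) * (1.0 - s_g),
            )
        )
    ranked.sort(key=lambda s: (-s.s_tot, -s.br, s.node))
    return [replace(s, rank=i + 1) for i, s in enumerate(ranked)]


def write_bridge_scores(scores: Sequence[BridgeScore], path: str | os.PathLike[str]) -> None:
    frame = pd.DataFrame(
        [
            {
                "node": s.node,
                "rwbc": s.rwbc,
                "bcoeff": s.bcoeff,
                "br": s.br,
                "count_kegg": s.count_kegg,
                "count_go": s.count_go,
                "s_kegg": s.s_kegg,
                "s_go": s.s_go,
                "s_tot": s.s_tot,
                "rank": s.rank,
            }
            for s in scores
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
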