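"""Weighted protein-interaction network assembly from STRING-style edge tables.

The pipeline starts from a small set of literature-curated *seed* genes and a
STRING-dialect protein-links table (tab-separated, one row per protein pair,
one column per evidence channel plus a combined confidence score). Edges are
kept only when the combined confidence exceeds a threshold (default 0.7, the
conventional "high confidence" STRING cut) and at least one of the required
evidence channels (default: experimental and database) supports the pair.
The network is then the subgraph induced on the seeds and their direct
neighbors, with confidence scores as edge weights.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

__all__ = [
    "EvidenceEdge",
    "WeightedNetwork",
    "read_string_links",
    "read_seed_list",
    "build_network",
    "degree_threshold",
    "write_network",
    "read_network",
]

#: Evidence channels an edge must be supported by (any one suffices by default).
DEFAULT_CHANNELS = ("experimental", "database")

#: STRING's "high confidence" combined-score cut; edges must score strictly above.
DEFAULT_MIN_SCORE = 0.7

_ID_COLUMNS = (("protein_a", "protein_b"), ("protein1", "protein2"))


@dataclass(frozen=True)
class EvidenceEdge:
    """One deduplicated undirected protein pair with per-channel confidences."""

    protein_a: str
    protein_b: str
    channel_scores: Mapping[str, float]
    combined_score: float

    def key(self) -> tuple[str, str]:
        """Canonical unordered pair key."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)


@dataclass
class WeightedNetwork:
    """Undirected simple graph of gene symbols with confidence weights.

    ``graph`` is a :class:`networkx.Graph` whose edges carry a ``weight``
    attribute in (0, 1]. ``seeds`` flags the input genes the network was
    expanded from; ``externally_supplied`` marks graphs read back from disk
    whose seed-adjacency provenance is unknown.
    """

    graph: nx.Graph
    seeds: frozenset[str] = frozenset()
    externally_supplied: bool = False

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def _detect_scale(raw: pd.Series, values: pd.Series) -> float:
    """STRING publishes scores either as integers 0-999 or floats in [0, 1].

    A column written entirely as integer literals (or containing any value
    above 1) is the milli-score dialect and is divided by 1000; otherwise
    values are taken as already being probabilities.
    """
    text = raw.dropna().astype(str).str.strip()
    if len(text) and text.str.fullmatch(r"[+-]?\d+").all():
        return 1000.0
    if values.max() > 1.0:
        return 1000.0
    return 1.0


def read_string_links(
    path: str | os.PathLike[str] | io.TextIOBase,
    min_score: float = DEFAULT_MIN_SCORE,
    required_channels: Sequence[str] = DEFAULT_CHANNELS,
    require_all: bool = False,
) -> list[EvidenceEdge]:
    """Read and filter a STRING-dialect protein-links table.

    Parameters
    ----------
    path
        TSV file with a header row naming two protein columns
        (``protein_a``/``protein_b`` or STRING's ``protein1``/``protein2``),
        per-channel score columns, and ``combined_score``.
    min_score
        Keep edges with ``combined_score`` strictly greater than this.
    required_channels
        Evidence channels that must support the edge (score > 0).
    require_all
        If True every required channel must be positive; by default any one
        positive channel qualifies the edge.

    Returns
    -------
    list of :class:`EvidenceEdge`, deduplicated over unordered pairs keeping
    the maximum combined score, self-loops dropped.
    """
    if not 0.0 <= min_score <= 1.0:
        raise UsageError(f"min_score must be in [0, 1], got {min_score}")
    table = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    table.columns = [c.strip() for c in table.columns]

    id_cols = next((pair for pair in _ID_COLUMNS if set(pair) <= set(table.columns)), None)
    if id_cols is None:
        raise FormatError(
            "missing protein identifier columns: expected 'protein_a'/'protein_b' "
            "or 'protein1'/'protein2'"
        )
    if "combined_score" not in table.columns:
        raise FormatError("missing required column 'combined_score'")
    score_cols = [c for c in table.columns if c not in id_cols]
    for channel in required_channels:
        if channel not in score_cols:
            raise FormatError(f"missing required column {channel!r}")

    numeric = {}
    for col in score_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.index[values.isna() & table[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"non-numeric score in column {col!r} at line {bad[0] + 2}: "
                f"{table[col].iloc[bad[0]]!r}"
            )
        scale = _detect_scale(table[col], values)
        numeric[col] = values.astype(float) / scale
        if (numeric[col] < 0).any() or (numeric[col] > 1).any():
            raise FormatError(f"scores in column {col!r} fall outside [0, 1] after scaling")

    best: dict[tuple[str, str], EvidenceEdge] = {}
    combined = numeric["combined_score"]
    channels = {c: numeric[c] for c in score_cols if c != "combined_score"}
    for i in range(len(table)):
        a = str(table[id_cols[0]].iloc[i]).strip()
        b = str(table[id_cols[1]].iloc[i]).strip()
        if a == b:
            continue
        score = float(combined.iloc[i])
        if not score > min_score:
            continue
        support = [channels[c].iloc[i] > 0 for c in required_channels]
        if not (all(support) if require_all else any(support)):
            continue
        edge = EvidenceEdge(
            protein_a=a,
            protein_b=b,
            channel_scores={c: float(col.iloc[i]) for c, col in channels.items()},
            combined_score=score,
        )
        key = edge.key()
        if key not in best or score > best[key].combined_score:
            best[key] = edge
    return [best[k] for k in sorted(best)]


def read_seed_list(path: str | os.PathLike[str]) -> list[str]:
    """Read one gene symbol per line; ``#`` starts a comment."""
    seeds = []
    with open(path) as handle:
        for line in handle:
            symbol = line.split("#", 1)[0].strip()
            if symbol:
                seeds.append(symbol)
    return seeds


def build_network(seeds: Sequence[str], edges: Iterable[EvidenceEdge]) -> WeightedNetwork:
    """Expand seeds into the induced weighted network.

    The node set is the seeds plus every direct neighbor of a seed through a
    qualifying edge; the edge set is *all* qualifying edges between those
    nodes (induced subgraph), so neighbor-neighbor edges are retained. Seeds
    absent from every edge stay in the network as isolated flagged nodes.
    """
    if not seeds:
        raise UsageError("seed list is empty")
    seed_set = frozenset(seeds)
    edge_list = list(edges)
    keep = set(seed_set)
    for e in edge_list:
        if e.protein_a in seed_set or e.protein_b in seed_set:
            keep.add(e.protein_a)
            keep.add(e.protein_b)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(keep))
    for e in edge_list:
        if e.protein_a in keep and e.protein_b in keep:
            graph.add_edge(e.protein_a, e.protein_b, weight=e.combined_score)
    return WeightedNetwork(graph=graph, seeds=seed_set)


def degree_threshold(network: WeightedNetwork, percentile: float) -> float:
    """Percentile of the unweighted-degree distribution (linear interpolation).

    Callers select nodes with degree *strictly greater* than the returned
    value — the convention that turns a 90th-percentile rule into a strict
    "k > threshold" hub cut.
    """
    if network.number_of_nodes() < 2:
        raise UsageError("degree threshold needs a network with at least 2 nodes")
    if not 0 <= percentile <= 100:
        raise UsageError(f"percentile must be in [0, 100], got {percentile}")
    degrees = [d for _, d in network.graph.degree()]
    return float(np.percentile(degrees, percentile, method="linear"))


def write_network(
    network: WeightedNetwork,
    edge_path: str | os.PathLike[str],
    node_path: str | os.PathLike[str] | None = None,
) -> None:
    """Write the edge list (node_a, node_b, weight) and optional node table."""
    rows = [
        {"node_a": min(u, v), "node_b": max(u, v), "weight": round(d["weight"], 6)}
        for u, v, d in network.graph.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    edges.sort_values(["node_a", "node_b"]).to_csv(edge_path, sep="\t", index=False)
    if node_path is not None:
        nodes = pd.DataFrame(
            {
                "node": network.nodes,
                "is_seed": [n in network.seeds for n in network.nodes],
                "degree": [network.degree(n) for n in network.nodes],
            }
        )
        nodes.to_csv(node_path, sep="\t", index=False)


def read_network(
    edge_path: str | os.PathLike[str],
    node_path: str | os.PathLike[str] | None = None,
) -> WeightedNetwork:
    """Read a network written by :func:`write_network`.

    Without a node table the seed flags are unknown, so the graph is marked
    as externally supplied (isolated non-seed nodes cannot be recovered from
    the edge list alone).
    """
    edges = pd.read_csv(edge_path, sep="\t")
    for col in ("node_a", "node_b", "weight"):
        if col not in edges.columns:
            raise FormatError(f"edge list is missing column {col!r}")
    graph = nx.Graph()
    for a, b, w in edges[["node_a", "node_b", "weight"]].itertuples(index=False):
        graph.add_edge(str(a), str(b), weight=float(w))
    seeds: frozenset[str] = frozenset()
    if node_path is not None:
        nodes = pd.read_csv(node_path, sep="\t")
        graph.add_nodes_from(str(n) for n in nodes["node"])
        seeds = frozenset(str(n) for n, s in zip(nodes["node"], nodes["is_seed"]) if s)
    return WeightedNetwork(graph=graph, seeds=seeds, externally_supplied=node_path is None)
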