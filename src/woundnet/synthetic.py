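"""Deterministic synthetic data so every pipeline stage runs without downloads.

Three generator families mirror the real inputs:

* planted-module networks — a few dense modules of known membership joined by
  sparse cross edges and one or more low-degree *bridge* connectors, emitted
  either as a ready :class:`~woundnet.network.WeightedNetwork` or as a
  STRING-dialect protein-links table;
* toy KGML documents that round-trip through the pathway parser;
* long-format expression tables with stated per-condition log2 effects.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .enrich import AnnotationCatalog, CatalogTerm
from .errors import UsageError
from .network import WeightedNetwork

__all__ = [
    "PlantedNetworkSpec",
    "PlantedGroundTruth",
    "make_planted_network",
    "network_to_string_table",
    "make_toy_kgml",
    "make_random_pathway",
    "make_expression_table",
    "make_module_catalog",
]

#: Default experimental layout: scratch-wound assay with and without treatment,
#: sampled at two timepoints with three biological replicates per group.
DEFAULT_CONDITIONS = (
    "noScratch-noTreat",
    "noScratch-yesTreat",
    "yesScratch-noTreat",
    "yesScratch-yesTreat",
)
DEFAULT_TIMEPOINTS = ("1h", "5h")


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted-module benchmark network.

    In-module edge weights default to the (0.7, 1.0) high-confidence band so
    they survive the STRING score filter; cross-module weights default to the
    (0.4, 0.7) band *below* the filter, so reading the emitted STRING table
    through the standard filter exercises edge rejection. Bridge connectors
    attach to ``bridge_degree`` random nodes in each of two modules with
    high-confidence weights.
    """

    n_modules: int = 2
    module_size: int = 20
    p_in: float = 0.9
    p_out: float = 0.02
    weight_in: tuple[float, float] = (0.7, 1.0)
    weight_out: tuple[float, float] = (0.4, 0.7)
    n_bridge_nodes: int = 1
    bridge_degree: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size < 3:
            raise UsageError("module_size must be >= 3")
        if self.n_modules < 1:
            raise UsageError("need at least one module")
        for p in (self.p_in, self.p_out):
            if not 0 <= p <= 1:
                raise UsageError("edge probabilities must lie in [0, 1]")
        for lo, hi in (self.weight_in, self.weight_out):
            if not (0 < lo <= hi <= 1):
                raise UsageError("weight ranges must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class PlantedGroundTruth:
    modules: tuple[frozenset[str], ...]
    bridges: tuple[str, ...]


def make_planted_network(
    spec: PlantedNetworkSpec,
) -> tuple[WeightedNetwork, PlantedGroundTruth]:
    """Generate the planted-module network and its ground truth.

    Module nodes are named ``M<module>N<index>``; bridges ``XBR<index>``
    (the X prefix keeps them lexicographically apart from module nodes).
    """
    rng = np.random.default_rng(spec.seed)
    graph = nx.Graph()
    modules: list[frozenset[str]] = []
    for m in range(spec.n_modules):
        names = [f"M{m + 1}N{i:03d}" for i in range(spec.module_size)]
        graph.add_nodes_from(names)
        modules.append(frozenset(names))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if rng.random() < spec.p_in:
                    w = rng.uniform(*spec.weight_in)
                    graph.add_edge(names[i], names[j], weight=float(w))
    module_lists = [sorted(m) for m in modules]
    for a in range(spec.n_modules):
        for b in range(a + 1, spec.n_modules):
            for u in module_lists[a]:
                for v in module_lists[b]:
                    if rng.random() < spec.p_out:
                        w = rng.uniform(*spec.weight_out)
                        graph.add_edge(u, v, weight=float(w))
    bridges = []
    for k in range(spec.n_bridge_nodes):
        name = f"XBR{k + 1}"
        bridges.append(name)
        graph.add_node(name)
        pair = rng.choice(spec.n_modules, size=2, replace=False) if spec.n_modules > 1 else [0, 0]
        for m in sorted(set(int(x) for x in pair)):
            targets = rng.choice(
                module_lists[m], size=min(spec.bridge_degree, spec.module_size), replace=False
            )
            for v in targets:
                w = rng.uniform(*spec.weight_in)
                graph.add_edge(name, str(v), weight=float(w))
    truth = PlantedGroundTruth(modules=tuple(modules), bridges=tuple(bridges))
    return WeightedNetwork(graph=graph, seeds=frozenset()), truth


def network_to_string_table(
    network: WeightedNetwork,
    path: str | os.PathLike[str] | None = None,
    style: str = "float",
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a STRING-dialect protein-links table for the network.

    Each edge's combined score is its weight; the experimental channel equals
    the weight and the database channel a random fraction of it, so every
    edge qualifies under the any-required-channel rule. ``style`` selects the
    float [0, 1] dialect or the integer 0-999 dialect.
    """
    if style not in ("float", "int"):
        raise UsageError("style must be 'float' or 'int'")
    rng = np.random.default_rng(seed)
    rows = []
    for u, v, d in sorted(network.graph.edges(data=True)):
        w = d["weight"]
        database = round(float(w * rng.uniform(0.3, 0.9)), 3)
        textmining = round(float(rng.uniform(0.0, 0.3)), 3)
        record = {
            "protein_a": min(u, v),
            "protein_b": max(u, v),
            "experimental": round(float(w), 3),
            "database": database,
            "textmining": textmining,
            "combined_score": round(float(w), 3),
        }
        rows.append(record)
    frame = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "experimental", "database",
                       "textmining", "combined_score"]
    )
    if style == "int":
        for col in ("experimental", "database", "textmining", "combined_score"):
            frame[col] = (frame[col] * 1000).round().astype(int)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def make_toy_kgml(
    motifs: Sequence[tuple[str, str, int]],
    pathway_name: str = "synthetic pathway",
    groups: Mapping[str, Sequence[str]] | None = None,
) -> str:
    """Write a minimal well-formed KGML document encoding signed regulations.

    ``motifs`` lists (source, target, sign) with sign +1 for activation and
    -1 for inhibition; sources/targets may name a group declared in
    ``groups`` (group-id -> member gene names), which the parser expands.
    Round-trips through :func:`woundnet.boolnet.parse_kgml`.
    """
    groups = dict(groups or {})
    genes: list[str] = []
    for src, tgt, sign in motifs:
        if sign not in (+1, -1):
            raise UsageError(f"sign must be +1 or -1 in motif {(src, tgt, sign)}")
        for name in (src, tgt):
            if name not in groups and name not in genes:
                genes.append(name)
    for members in groups.values():
        for name in members:
            if name not in genes:
                genes.append(name)

    root = etree.Element(
        "pathway", name="path:synthetic", org="syn", number="00000", title=pathway_name
    )
    ids: dict[str, str] = {}
    next_id = 1
    for gene in genes:
        ids[gene] = str(next_id)
        entry = etree.SubElement(
            root, "entry", id=ids[gene], name=f"syn:{gene}", type="gene"
        )
        etree.SubElement(entry, "graphics", name=f"{gene}, {gene}_alias", type="rectangle")
        next_id += 1
    for group_name, members in groups.items():
        ids[group_name] = str(next_id)
        entry = etree.SubElement(
            root, "entry", id=ids[group_name], name="undefined", type="group"
        )
        for member in members:
            etree.SubElement(entry, "component", id=ids[member])
        next_id += 1
    for src, tgt, sign in motifs:
        relation = etree.SubElement(
            root, "relation", entry1=ids[src], entry2=ids[tgt], type="PPrel"
        )
        etree.SubElement(
            relation,
            "subtype",
            name="activation" if sign > 0 else "inhibition",
            value="-->" if sign > 0 else "--|",
        )
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def make_random_pathway(
    n_nodes: int = 44,
    n_edges: int = 49,
    activation_fraction: float = 0.8,
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Random signed regulation list at a stated scale (default 44 nodes,
    49 edges, mirroring a mid-sized signaling pathway)."""
    if n_edges > n_nodes * (n_nodes - 1):
        raise UsageError("too many edges for the number of nodes")
    if n_edges < n_nodes - 1:
        raise UsageError("need at least n_nodes - 1 edges to touch every node")
    rng = np.random.default_rng(seed)
    names = [f"G{i:02d}" for i in range(n_nodes)]
    # random arborescence backbone so every node participates in the pathway
    order = rng.permutation(n_nodes)
    pairs: set[tuple[int, int]] = set()
    for pos in range(1, n_nodes):
        parent = int(order[rng.integers(0, pos)])
        pairs.add((parent, int(order[pos])))
    while len(pairs) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            pairs.add((int(i), int(j)))
    motifs = []
    for i, j in sorted(pairs):
        sign = 1 if rng.random() < activation_fraction else -1
        motifs.append((names[i], names[j], sign))
    return motifs


def make_expression_table(
    genes: Sequence[str],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    replicates: int = 3,
    effects: Mapping[tuple[str, str], float] | None = None,
    baseline: float = 5.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format log2 expression table with planted effects.

    ``effects`` maps (gene, condition) or (gene, condition, timepoint) keys
    to a log2 fold change added on top of the baseline. Values are baseline
    + effect + Gaussian noise; three replicates per group by default.
    """
    if replicates < 2:
        raise UsageError("need at least 2 replicates per group for testing")
    effects = dict(effects or {})
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for condition in conditions:
            for timepoint in timepoints:
                effect = effects.get(
                    (gene, condition, timepoint), effects.get((gene, condition), 0.0)
                )
                for rep in range(1, replicates + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "timepoint": timepoint,
                            "replicate": rep,
                            "log2_expression": baseline + effect + noise,
                        }
                    )
    return pd.DataFrame(rows, columns=list(
        ("gene", "condition", "timepoint", "replicate", "log2_expression")
    ))


def make_module_catalog(
    truth: PlantedGroundTruth,
    background: Iterable[str],
    n_noise_terms: int = 4,
    noise_term_size: int = 8,
    n_background_extra: int = 1000,
    seed: int = 0,
) -> tuple[AnnotationCatalog, frozenset[str], frozenset[str]]:
    """Annotation catalog aligned with the planted modules.

    One KEGG pathway and one GO term per module, containing the module's
    member genes plus every bridge connector (bridges span modules, so they
    carry all module annotations), plus a few random noise terms. The
    background embeds the supplied genes in ``n_background_extra`` filler
    genes, mimicking a genome-wide annotation universe of which the network
    is a small, strongly enriched subset. Returns the catalog together with
    the KEGG and GO reference id sets (the module-derived terms play the
    role of the process-relevant references).
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(background))
    universe += [f"BG{i:05d}" for i in range(n_background_extra)]
    terms = []
    ref_kegg = set()
    ref_go = set()
    for i, module in enumerate(truth.modules, start=1):
        genes = frozenset(module) | frozenset(truth.bridges)
        kegg_id = f"path{i:05d}"
        go_id = f"GO:{i:07d}"
        terms.append(CatalogTerm(kegg_id, "KEGG", f"module {i} pathway", genes))
        terms.append(CatalogTerm(go_id, "GO", f"module {i} process", genes))
        ref_kegg.add(kegg_id)
        ref_go.add(go_id)
    for j in range(n_noise_terms):
        members = frozenset(
            str(g) for g in rng.choice(universe, size=min(noise_term_size, len(universe)),
                                       replace=False)
        )
        terms.append(CatalogTerm(f"path9{j:04d}", "KEGG", f"noise pathway {j}", members))
        terms.append(CatalogTerm(f"GO:9{j:06d}", "GO", f"noise process {j}", members))
    catalog = AnnotationCatalog(
        terms=tuple(terms),
        background=frozenset(universe) | frozenset(truth.bridges)
        | frozenset().union(*(t.genes for t in terms)),
    )
    return catalog, frozenset(ref_kegg), frozenset(ref_go)
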