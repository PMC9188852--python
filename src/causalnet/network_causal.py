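"""Confidence-weighted protein network with a directed causal overlay.

The undirected layer is the induced subgraph of a weighted interaction edge
list (0-1000 combined confidence scores, stored as weights on [0, 1]) on a
submitted protein set. The causal layer overlays directed protein->protein
edges carrying a free-text effect and a mode-of-interaction (moi) category
using the same 1/2/3 coding as the drug-target profiles: 1 positive
modulation, 2 negative modulation, 3 undirected/unknown. The two layers are
kept separate in the data model and in GraphML output (edge attribute
``layer``), since the confidence and causal evidence come from different
resources and are not merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .causal_profile import MoACategory, UnmappedTermError
from .io_formats import SignorRecord, StringEdge

logger = logging.getLogger("causalnet")

DEFAULT_MIN_SCORE = 400  # conventional "medium confidence" threshold


@dataclass(frozen=True)
class CausalEdge:
    """Directed protein->protein causal interaction."""

    source_id: str
    target_id: str
    effect: str
    moi: MoACategory

    def __post_init__(self):
        if self.moi == MoACategory.INACTIVE:
            raise ValueError("mode of interaction must be 1, 2 or 3")


@dataclass
class ProteinNetwork:
    """Undirected confidence layer plus directed causal overlay."""

    graph: nx.Graph
    causal_edges: list[CausalEdge] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]


def load_signor_effects() -> dict[str, MoACategory]:
    """Packaged non-directional effect terms (directional ones match by prefix)."""
    with resources.as_file(resources.files("causalnet.data").joinpath("signor_effects.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return {str(t).strip().casefold(): MoACategory(int(c)) for t, c in zip(df.effect, df.category)}


def map_effect_to_moi(
    effect: str, mapping: Mapping[str, MoACategory] | None = None
) -> MoACategory:
    """Map a causal-interaction effect string to a mode-of-interaction category.

    ``up-regulates*`` effects are positive (1), ``down-regulates*`` negative
    (2); non-directional effects ("form complex", "unknown", "binding") are
    category 3 via the packaged table. Anything else raises
    :class:`UnmappedTermError`.
    """
    mapping = mapping if mapping is not None else load_signor_effects()
    key = str(effect).strip().casefold()
    if key in mapping:
        return mapping[key]
    if key.startswith("up-regulates"):
        return MoACategory.POSITIVE
    if key.startswith("down-regulates"):
        return MoACategory.NEGATIVE
    raise UnmappedTermError(effect, "causal effect")


def build_network(
    proteins: Iterable[str],
    edges: list[StringEdge],
    min_score: int = DEFAULT_MIN_SCORE,
) -> ProteinNetwork:
    """Induced confidence subgraph on ``proteins``.

    Edges with ``combined_score >= min_score`` and both endpoints in the
    protein set are kept with weight ``combined_score / 1000``; submitted
    proteins without any surviving edge remain as isolated nodes.
    """
    protein_set = set(proteins)
    if not protein_set:
        raise ValueError("protein set must be non-empty")
    if not 0 <= min_score <= 1000:
        raise ValueError("min_score must be in [0, 1000]")
    graph = nx.Graph()
    graph.add_nodes_from(sorted(protein_set))
    kept = 0
    for edge in edges:
        if edge.combined_score < min_score:
            continue
        if edge.protein_a not in protein_set or edge.protein_b not in protein_set:
            continue
        graph.add_edge(edge.protein_a, edge.protein_b, weight=edge.combined_score / 1000.0)
        kept += 1
    logger.info(
        "network: %d nodes, %d confidence edges (min_score=%d)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        min_score,
    )
    return ProteinNetwork(graph=graph)


def overlay_causal(
    network: ProteinNetwork,
    records: list[SignorRecord],
    mapping: Mapping[str, MoACategory] | None = None,
) -> ProteinNetwork:
    """Overlay directed causal edges onto the network (in place, also returned).

    Only protein-protein rows whose endpoints are both network nodes are kept;
    duplicate (source, target, effect) rows collapse to one edge. No nodes are
    ever added.
    """
    mapping = mapping if mapping is not None else load_signor_effects()
    nodes = network.nodes
    seen: set[tuple[str, str, str]] = set()
    dropped_type = dropped_outside = 0
    for record in records:
        if record.type_a.casefold() != "protein" or record.type_b.casefold() != "protein":
            dropped_type += 1
            continue
        if record.id_a not in nodes or record.id_b not in nodes:
            dropped_outside += 1
            continue
        key = (record.id_a, record.id_b, record.effect)
        if key in seen:
            continue
        seen.add(key)
        network.causal_edges.append(
            CausalEdge(
                source_id=record.id_a,
                target_id=record.id_b,
                effect=record.effect,
                moi=map_effect_to_moi(record.effect, mapping),
            )
        )
    logger.info(
        "causal overlay: %d edges kept, %d non-protein rows dropped, %d outside network",
        len(seen),
        dropped_type,
        dropped_outside,
    )
    return network


def to_multigraph(
    network: ProteinNetwork, gene_names: Mapping[str, str] | None = None
) -> nx.MultiDiGraph:
    """Export both layers into one GraphML-serializable multigraph.

    Confidence edges appear once (endpoints in sorted order) with
    ``layer="confidence"``; causal edges keep their direction with
    ``layer="causal"``, effect text and moi.
    """
    out = nx.MultiDiGraph()
    for node in sorted(network.nodes):
        out.add_node(node, gene_name=(gene_names or {}).get(node, node))
    for a, b, data in sorted(network.graph.edges(data=True)):
        a, b = sorted((a, b))
        out.add_edge(a, b, layer="confidence", weight=data["weight"])
    for edge in network.causal_edges:
        out.add_edge(
            edge.source_id,
            edge.target_id,
            layer="causal",
            effect=edge.effect,
            moi=int(edge.moi),
        )
    return out
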