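"""Marker interactome: confidence-thresholded graph, subnetworks, centrality.

Marker proteins are mapped onto a STRING-style interaction edge list. Edges
at or above the confidence threshold (default 0.4, "medium") induce a graph
on the markers; markers left without any qualifying edge are excluded from
the map and reported separately as unmapped. Connected components are
decomposed into functional subnetworks — within a component, all nodes
sharing a functional label form one subnetwork, and a subnetwork is
"isolated" when its component contains no other label. Hub proteins are
ranked by shortest-path betweenness.
"""

from __future__ import annotations

from collections.abc import Mapping, Set
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .markers import MarkerSet

DEFAULT_MIN_CONFIDENCE = 0.4
EDGE_COLUMNS = ("protein_a", "protein_b", "confidence")


@dataclass
class InteractionGraph:
    """Confidence-thresholded interaction graph on marker proteins.

    ``unmapped`` holds markers with no retained edge (absent from the
    graph's node set).
    """

    graph: nx.Graph
    unmapped: frozenset[str]
    min_confidence: float

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class Subnetwork:
    """Maximal same-label node set within one connected component."""

    label: str
    members: frozenset[str]
    component_id: int
    isolated: bool

    @property
    def size(self) -> int:
        return len(self.members)


def normalize_confidences(values) -> np.ndarray:
    """Map confidences to [0, 1]; STRING 0-1000 scores (any value > 1) are
    divided by 1000."""
    conf = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(conf)) or conf.min(initial=0) < 0:
        raise ValidationError("confidences must be finite and >= 0")
    if conf.size and conf.max() > 1:
        if conf.max() > 1000:
            raise ValidationError(
                f"confidence {conf.max()} outside both the 0-1 and 0-1000 scales")
        conf = conf / 1000.0
    return conf


def build_marker_graph(
    markers: MarkerSet | Set[str],
    edges: pd.DataFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> InteractionGraph:
    """Induced subgraph of the edge list on the marker proteins.

    Edges with confidence >= ``min_confidence`` (inclusive) between two
    markers are retained; duplicate unordered pairs keep the highest
    confidence; self-loops are dropped. Markers left with degree zero are
    excluded from the node set and listed as unmapped.
    """
    marker_ids = frozenset(
        markers.proteins if isinstance(markers, MarkerSet) else markers)
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValidationError(f"edge list missing columns: {', '.join(missing)}")

    graph = nx.Graph()
    if len(edges):
        conf = normalize_confidences(edges["confidence"])
        frame = edges.assign(confidence=conf)
        frame = frame[frame["protein_a"] != frame["protein_b"]]
        frame = frame[frame["protein_a"].isin(marker_ids)
                      & frame["protein_b"].isin(marker_ids)]
        av = frame["protein_a"].astype(str).to_numpy(dtype=object)
        bv = frame["protein_b"].astype(str).to_numpy(dtype=object)
        swap = av > bv
        frame = frame.assign(protein_a=np.where(swap, bv, av),
                             protein_b=np.where(swap, av, bv))
        frame = (frame.sort_values("confidence")
                 .drop_duplicates(["protein_a", "protein_b"], keep="last"))
        frame = frame[frame["confidence"] >= min_confidence]
        for row in frame.itertuples(index=False):
            graph.add_edge(row.protein_a, row.protein_b,
                           confidence=float(row.confidence))
    return InteractionGraph(
        graph=graph,
        unmapped=marker_ids - set(graph.nodes),
        min_confidence=min_confidence,
    )


def decompose_subnetworks(
    graph: InteractionGraph,
    category_map: Mapping[str, str],
) -> list[Subnetwork]:
    """Partition graph nodes into (component, functional label) subnetworks.

    Every node needs a label in ``category_map``. Components are numbered
    by size descending (ties by smallest member name); subnetworks are
    sorted by size descending, then label.
    """
    unlabeled = sorted(n for n in graph.graph.nodes if n not in category_map)
    if unlabeled:
        raise ConfigurationError(
            f"nodes without functional label: {', '.join(unlabeled)}")
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph.graph)),
        key=lambda c: (-len(c), c[0]),
    )
    subnetworks: list[Subnetwork] = []
    for comp_id, comp in enumerate(components):
        by_label: dict[str, set[str]] = {}
        for node in comp:
            by_label.setdefault(category_map[node], set()).add(node)
        isolated = len(by_label) == 1
        for label, members in by_label.items():
            subnetworks.append(Subnetwork(
                label=label,
                members=frozenset(members),
                component_id=comp_id,
                isolated=isolated,
            ))
    return sorted(subnetworks, key=lambda s: (-s.size, s.label))


def rank_centrality(graph: InteractionGraph) -> pd.DataFrame:
    """Unweighted degree and shortest-path betweenness per node.

    Betweenness is the raw (unnormalised) count of shortest paths through
    the node. Ranking: betweenness descending, ties by degree descending,
    then protein name.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["protein_id", "degree", "betweenness"])
    betweenness = nx.betweenness_centrality(g, normalized=False)
    table = pd.DataFrame({
        "protein_id": list(g.nodes),
        "degree": [g.degree(n) for n in g.nodes],
        "betweenness": [betweenness[n] for n in g.nodes],
    })
    return (table.sort_values(
        ["betweenness", "degree", "protein_id"],
        ascending=[False, False, True], kind="mergesort")
        .reset_index(drop=True))


def node_table(
    graph: InteractionGraph,
    subnetworks: list[Subnetwork] | None = None,
) -> pd.DataFrame:
    """Per-node export: component, subnetwork, degree, betweenness, isolated."""
    ranking = rank_centrality(graph)
    if subnetworks:
        comp = {n: s.component_id for s in subnetworks for n in s.members}
        label = {n: s.label for s in subnetworks for n in s.members}
        iso = {n: s.isolated for s in subnetworks for n in s.members}
        ranking["component"] = ranking["protein_id"].map(comp)
        ranking["subnetwork"] = ranking["protein_id"].map(label)
        ranking["isolated"] = ranking["protein_id"].map(iso)
    return ranking
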