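"""Multilayer association networks and their degree statistics.

Two graph shapes are used: the tripartite herb-compound-target (H-C-T)
network and the bipartite target-pathway (T-P) network. Both are
undirected simple graphs whose edges may only connect adjacent layers
(herb-compound, compound-target, target-pathway). Exports are
Cytoscape-compatible: SIF edge lists with a node-attribute sidecar, and
GraphML with layer and degree attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .errors import ValidationError

__all__ = [
    "NetworkGraph",
    "build_hct",
    "build_tp",
    "NetworkSummary",
    "summarize",
    "write_sif",
    "read_sif",
    "write_graphml",
]

LAYERS = ("herb", "compound", "target", "pathway")
_ADJACENT = {
    frozenset({"herb", "compound"}): "hc",
    frozenset({"compound", "target"}): "ct",
    frozenset({"target", "pathway"}): "tp",
}


class NetworkGraph:
    """Undirected simple graph with typed layers and adjacency rules.

    Thin wrapper around :class:`networkx.Graph` that rejects self-loops,
    intra-layer edges and edges between non-adjacent layers, and tags
    each edge with its interaction label (``hc`` / ``ct`` / ``tp``).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, layer: str) -> None:
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer {layer!r} for node {node_id!r}")
        existing = self._g.nodes.get(node_id)
        if existing is not None and existing["layer"] != layer:
            raise ValidationError(
                f"node {node_id!r} already present with layer {existing['layer']!r}"
            )
        self._g.add_node(node_id, layer=layer)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValidationError(f"self-loop rejected: {u!r}")
        for n in (u, v):
            if n not in self._g:
                raise ValidationError(f"unknown node {n!r}; add nodes before edges")
        pair = frozenset({self._g.nodes[u]["layer"], self._g.nodes[v]["layer"]})
        label = _ADJACENT.get(pair)
        if label is None:
            raise ValidationError(
                f"edge {u!r}-{v!r} connects non-adjacent layers {sorted(pair)}"
            )
        self._g.add_edge(u, v, interaction=label)

    # -- queries ----------------------------------------------------------
    def degree(self, node_id: str) -> int:
        """Number of incident edges; unknown nodes are an error."""
        if node_id not in self._g:
            raise ValidationError(f"unknown node {node_id!r}")
        return int(self._g.degree[node_id])

    def nodes(self, layer: str | None = None) -> list[str]:
        if layer is None:
            return sorted(self._g.nodes)
        return sorted(n for n, d in self._g.nodes(data=True) if d["layer"] == layer)

    def edges(self, interaction: str | None = None) -> list[tuple[str, str]]:
        out = []
        for u, v, d in self._g.edges(data=True):
            if interaction is None or d["interaction"] == interaction:
                a, b = sorted((u, v))
                out.append((a, b))
        return sorted(out)

    def layer_of(self, node_id: str) -> str:
        if node_id not in self._g:
            raise ValidationError(f"unknown node {node_id!r}")
        return self._g.nodes[node_id]["layer"]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkGraph):
            return NotImplemented
        return (
            {n: d["layer"] for n, d in self._g.nodes(data=True)}
            == {n: d["layer"] for n, d in other._g.nodes(data=True)}
            and self.edges() == other.edges()
        )


def build_hct(
    membership: dict[str, list[str]],
    ct_edges: list[tuple[str, str]],
) -> NetworkGraph:
    """Assemble the herb-compound-target network.

    ``membership`` maps each herb to its active compounds; ``ct_edges``
    are (compound, target) pairs. Every compound appearing in an edge
    must belong to some herb, otherwise the offenders are reported.
    Duplicate pairs collapse (simple graph).
    """
    known = {c for comps in membership.values() for c in comps}
    orphans = sorted({c for c, _ in ct_edges} - known)
    if orphans:
        raise ValidationError(
            f"compounds in ct_edges missing from herb membership: {orphans}"
        )
    g = NetworkGraph()
    for herb, comps in membership.items():
        g.add_node(herb, "herb")
        for c in comps:
            g.add_node(c, "compound")
            g.add_edge(herb, c)
    for c, t in ct_edges:
        g.add_node(t, "target")
        g.add_edge(c, t)
    return g


def build_tp(tp_edges: list[tuple[str, str]]) -> NetworkGraph:
    """Assemble the bipartite target-pathway network from (gene, pathway)
    pairs, typically the annotated-overlap pairs of the selected enriched
    pathways."""
    g = NetworkGraph()
    for gene, pathway in tp_edges:
        g.add_node(gene, "target")
        g.add_node(pathway, "pathway")
        g.add_edge(gene, pathway)
    return g


@dataclass(frozen=True)
class NetworkSummary:
    """Headline statistics of an H-C-T (or T-P) graph.

    ``targets_per_compound`` is the conventional summary ratio
    (unique targets / unique compounds, 2 decimals); the true mean
    compound degree over compound-target edges is reported alongside,
    since for dense networks the two differ substantially.
    """

    ct_edge_count: int
    n_compounds: int
    n_targets: int
    targets_per_compound: float  # unique-target ratio, 2 dp
    mean_compound_degree: float  # over ct edges only
    pct_targets_multi_compound: float  # degree >= 2, 1 dp
    top_nodes: dict[str, list[tuple[str, int]]]  # layer -> [(node, degree)]


def summarize(g: NetworkGraph, top_k: int = 5) -> NetworkSummary:
    """Compute the summary statistics over compound-target edges only
    (herb edges are display structure, not interactions)."""
    ct = g.edges("ct")
    # edges() returns lexicographically ordered pairs; orient by layer
    ct_pairs = []
    for a, b in ct:
        if g.layer_of(a) == "compound":
            ct_pairs.append((a, b))
        else:
            ct_pairs.append((b, a))
    compounds = sorted({c for c, _ in ct_pairs})
    targets = sorted({t for _, t in ct_pairs})

    cdeg = {c: 0 for c in compounds}
    tdeg = {t: 0 for t in targets}
    for c, t in ct_pairs:
        cdeg[c] += 1
        tdeg[t] += 1

    n_c, n_t, n_e = len(compounds), len(targets), len(ct_pairs)
    ratio = round(n_t / n_c, 2) if n_c else 0.0
    mean_deg = n_e / n_c if n_c else 0.0
    multi = sum(1 for d in tdeg.values() if d >= 2)
    pct_multi = round(100.0 * multi / n_t, 1) if n_t else 0.0

    top: dict[str, list[tuple[str, int]]] = {}
    for layer in LAYERS:
        nodes = g.nodes(layer)
        if not nodes:
            continue
        ranked = sorted(((n, g.degree(n)) for n in nodes), key=lambda x: (-x[1], x[0]))
        top[layer] = ranked[:top_k]

    return NetworkSummary(
        ct_edge_count=n_e,
        n_compounds=n_c,
        n_targets=n_t,
        targets_per_compound=ratio,
        mean_compound_degree=mean_deg,
        pct_targets_multi_compound=pct_multi,
        top_nodes=top,
    )


# ---------------------------------------------------------------------------
# Cytoscape-compatible exports
# ---------------------------------------------------------------------------


def write_sif(g: NetworkGraph, path: str | Path, attrs_path: str | Path | None = None) -> None:
    """Write a SIF edge list (source <tab> interaction <tab> target) and,
    optionally, a node-attribute sidecar TSV (node_id, layer, degree).
    Output ordering is deterministic."""
    path = Path(path)
    lines = []
    for u, v in g.edges():
        label = _ADJACENT[frozenset({g.layer_of(u), g.layer_of(v)})]
        # orient edge upper-layer-first for stable, layer-faithful lines
        order = {layer: i for i, layer in enumerate(LAYERS)}
        a, b = (u, v) if order[g.layer_of(u)] <= order[g.layer_of(v)] else (v, u)
        lines.append(f"{a}\t{label}\t{b}\n")
    path.write_text("".join(sorted(lines)), encoding="utf-8")
    if attrs_path is not None:
        rows = ["node_id\tlayer\tdegree\n"]
        for n in g.nodes():
            rows.append(f"{n}\t{g.layer_of(n)}\t{g.degree(n)}\n")
        Path(attrs_path).write_text("".join(rows), encoding="utf-8")


_LABEL_LAYERS = {"hc": ("herb", "compound"), "ct": ("compound", "target"),
                 "tp": ("target", "pathway")}


def read_sif(path: str | Path) -> NetworkGraph:
    """Read a SIF file written by :func:`write_sif` back into a graph.

    Layer information is recovered from the interaction labels, so a
    write/read round trip reproduces the node and edge sets exactly
    (isolated nodes, which SIF cannot represent, excepted).
    """
    g = NetworkGraph()
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"{path}:{i}: malformed SIF line {line!r}")
        a, label, b = parts
        if label not in _LABEL_LAYERS:
            raise ValidationError(f"{path}:{i}: unknown interaction {label!r}")
        la, lb = _LABEL_LAYERS[label]
        g.add_node(a, la)
        g.add_node(b, lb)
        g.add_edge(a, b)
    return g


def write_graphml(g: NetworkGraph, path: str | Path) -> None:
    """GraphML export with layer and degree node attributes."""
    h = g.to_networkx()
    for n in h.nodes:
        h.nodes[n]["degree"] = int(h.degree[n])
    nx.write_graphml(h, str(path))
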