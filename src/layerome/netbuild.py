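"""Context-specific interaction network assembly and topology filters.

The interactome is the subgraph of a weighted functional-coupling edge list
induced on the differentially expressed genes. Self-loops are dropped,
duplicate unordered pairs are collapsed keeping the maximum confidence, and
nodes that lose all edges disappear. Small connected components are then
removed and, by default, only the largest component is kept (ties broken by
the component containing the lexicographically smallest gene id).

Networks are plain :class:`networkx.Graph` objects with a ``confidence``
edge attribute and an optional ``direction`` node attribute.
"""

from __future__ import annotations

import logging

import networkx as nx

logger = logging.getLogger(__name__)


def build_network(
    edge_list,
    de_genes,
    min_confidence: float = 0.0,
    directions: dict[str, str] | None = None,
) -> nx.Graph:
    """Induce the weighted network on ``de_genes``.

    ``edge_list`` is an iterable of (gene_a, gene_b, confidence) triples.
    Keeps only edges with both endpoints in ``de_genes`` and confidence >=
    ``min_confidence``; self-loops dropped; duplicates collapsed keeping
    the maximum confidence. Nodes with no surviving edge are not included.
    """
    if min_confidence < 0:
        raise ValueError("min_confidence must be >= 0")
    de = set(de_genes)
    g = nx.Graph()
    for a, b, w in edge_list:
        w = float(w)
        if a == b or a not in de or b not in de or w < min_confidence:
            continue
        if g.has_edge(a, b):
            if w > g[a][b]["confidence"]:
                g[a][b]["confidence"] = w
        else:
            g.add_edge(a, b, confidence=w)
    if directions:
        for n in g.nodes:
            g.nodes[n]["direction"] = directions.get(n, "")
    if g.number_of_nodes() == 0:
        logger.warning("build_network produced an empty network")
    logger.info(
        "build_network: %d nodes, %d edges (restricted to %d DE genes)",
        g.number_of_nodes(), g.number_of_edges(), len(de),
    )
    return g


def filter_components(
    network: nx.Graph,
    min_component_size: int = 5,
    keep_largest_only: bool = True,
) -> nx.Graph:
    """Drop small connected components; optionally keep only the largest.

    Components with fewer than ``min_component_size`` nodes are removed.
    With ``keep_largest_only`` the single largest component (by node count,
    ties broken by the smallest lexicographic member id) is retained.
    """
    if min_component_size < 1:
        raise ValueError("min_component_size must be >= 1")
    if network.number_of_nodes() == 0:
        logger.warning("filter_components on an empty network")
        return network.copy()
    comps = [c for c in nx.connected_components(network) if len(c) >= min_component_size]
    if keep_largest_only and comps:
        # largest first; equal sizes broken by the smallest member id
        comps.sort(key=lambda c: (-len(c), min(c)))
        comps = comps[:1]
    kept = set().union(*comps) if comps else set()
    dropped = network.number_of_nodes() - len(kept)
    logger.info("filter_components: kept %d nodes, dropped %d", len(kept), dropped)
    return network.subgraph(kept).copy()


# ---------------------------------------------------------------------------
# I/O: 3-column TSV edge list, SIF and GraphML exports
# ---------------------------------------------------------------------------

def read_edge_list(path) -> list[tuple[str, str, float]]:
    """Read a (gene_a, gene_b, confidence) TSV; malformed rows raise with line numbers."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("gene_a")):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: confidence {parts[2]!r} is not a number") from exc
            edges.append((parts[0], parts[1], w))
    return edges


def write_edge_list(network_or_edges, path) -> None:
    if isinstance(network_or_edges, nx.Graph):
        rows = sorted(
            (min(a, b), max(a, b), d["confidence"]) for a, b, d in network_or_edges.edges(data=True)
        )
    else:
        rows = sorted((min(a, b), max(a, b), w) for a, b, w in network_or_edges)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{format(w, '.6g')}\n")


def write_sif(network: nx.Graph, path) -> None:
    """Simple interaction format: 'geneA pp geneB' per edge."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in sorted((min(a, b), max(a, b)) for a, b in network.edges):
            fh.write(f"{a} pp {b}\n")


def write_graphml(network: nx.Graph, path) -> None:
    # rebuild with sorted nodes/edges so output bytes are order-invariant
    g = nx.Graph()
    g.add_nodes_from(sorted(network.nodes(data=True)))
    g.add_edges_from(sorted((min(a, b), max(a, b), d) for a, b, d in network.edges(data=True)))
    nx.write_graphml(g, path)
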