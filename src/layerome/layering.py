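"""Stratify the interactome into subcellular layers.

Every network node is placed in one of three canonical layers — plasma
membrane, cytoplasm, nucleus — from its localization records. Multi-
localized proteins are resolved by a configurable priority order (one node,
one layer). Nodes with no usable record inherit the majority layer of the
annotated nodes at minimal breadth-first distance, majority ties broken by
the priority order; provenance (annotated vs propagated) is recorded.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("plasma_membrane", "cytoplasm", "nucleus")
DEFAULT_PRIORITY = LAYERS

#: Raw localization label -> canonical layer (or "other"). Covers the
#: vocabulary emitted by the synthetic generator plus common curated terms.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "plasma membrane": "plasma_membrane",
    "plasma_membrane": "plasma_membrane",
    "cell membrane": "plasma_membrane",
    "cell surface": "plasma_membrane",
    "cytoplasm": "cytoplasm",
    "cytosol": "cytoplasm",
    "cytoplasmic vesicle": "cytoplasm",
    "endoplasmic reticulum": "cytoplasm",
    "golgi apparatus": "cytoplasm",
    "lysosome": "cytoplasm",
    "nucleus": "nucleus",
    "nucleolus": "nucleus",
    "nucleoplasm": "nucleus",
    "mitochondrion": "other",
    "extracellular": "other",
    "secreted": "other",
    "peroxisome": "other",
    "unknown": "other",
}


class UnknownLabelError(KeyError):
    """A localization label with no entry in the mapping table."""


@dataclass
class LocalizationMap:
    """gene -> ordered raw localization labels, plus the label mapping table."""

    records: dict[str, list[str]]
    label_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def labels(self, gene: str) -> list[str]:
        return self.records.get(gene, [])


def canonical_layer(
    localizations,
    priority=DEFAULT_PRIORITY,
    label_map: dict[str, str] | None = None,
) -> str | None:
    """Resolve raw labels to the highest-priority canonical layer, or None.

    Returns None when the gene has no label or only labels mapping to
    "other". Unknown labels raise :class:`UnknownLabelError`.
    """
    if sorted(priority) != sorted(LAYERS):
        raise ValueError("priority must be a permutation of the three canonical layers")
    label_map = label_map if label_map is not None else DEFAULT_LABEL_MAP
    mapped = set()
    for raw in localizations:
        key = raw.strip().lower()
        if key in LAYERS or key == "other":
            mapped.add(key)
            continue
        if key not in label_map:
            raise UnknownLabelError(f"no canonical mapping for localization label {raw!r}")
        mapped.add(label_map[key])
    for layer in priority:
        if layer in mapped:
            return layer
    return None


@dataclass
class LayeredInteractome:
    """A network with a total layer assignment and per-node provenance."""

    network: nx.Graph
    layer: dict[str, str]
    provenance: dict[str, str]

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(n for n, l in self.layer.items() if l == layer)


def assign_layers(
    network: nx.Graph,
    locmap: LocalizationMap,
    priority=DEFAULT_PRIORITY,
) -> LayeredInteractome:
    """Assign every node a layer; propagate to unannotated nodes by BFS.

    An unannotated node takes the majority layer among annotated nodes at
    its minimal BFS distance; majority ties are broken by the priority
    order. Nodes that cannot reach any annotated node raise an error.
    """
    annotated: dict[str, str] = {}
    for node in network.nodes:
        layer = canonical_layer(locmap.labels(node), priority, locmap.label_map)
        if layer is not None:
            annotated[node] = layer

    layer_of = dict(annotated)
    provenance = {n: "annotated" for n in annotated}
    orphans = []
    for node in sorted(network.nodes):
        if node in annotated:
            continue
        votes = _nearest_annotated(network, node, annotated)
        if not votes:
            orphans.append(node)
            continue
        counts = Counter(votes)
        best = max(counts.values())
        winner = next(l for l in priority if counts.get(l) == best)
        layer_of[node] = winner
        provenance[node] = "propagated"
    if orphans:
        raise ValueError(f"nodes with no annotated node reachable: {orphans}")
    n_prop = sum(1 for p in provenance.values() if p == "propagated")
    logger.info("assign_layers: %d annotated, %d propagated", len(annotated), n_prop)
    return LayeredInteractome(network=network, layer=layer_of, provenance=provenance)


def _nearest_annotated(network: nx.Graph, source: str, annotated: dict[str, str]) -> list[str]:
    """Layers of annotated nodes at minimal BFS distance from ``source``."""
    seen = {source}
    frontier = deque([source])
    while frontier:
        votes = []
        next_frontier = deque()
        for node in frontier:
            for nb in network.neighbors(node):
                if nb in seen:
                    continue
                seen.add(nb)
                next_frontier.append(nb)
                if nb in annotated:
                    votes.append(annotated[nb])
        if votes:
            return votes
        frontier = next_frontier
    return []


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 36.55 -> 36.6, not banker's 36.5)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def layer_distribution(layered: LayeredInteractome, directions: dict[str, str]) -> pd.DataFrame:
    """Per-layer up/down counts with percentages and a grand-total row.

    ``directions`` must cover every node. Percentage = 100*(up+down)/total,
    half-up rounded to one decimal.
    """
    missing = [n for n in layered.network.nodes if n not in directions]
    if missing:
        raise ValueError(f"nodes without a direction label: {sorted(missing)[:5]}...")
    counts = {layer: {"up": 0, "down": 0} for layer in LAYERS}
    for node in layered.network.nodes:
        d = directions[node]
        if d in ("up", "down"):
            counts[layered.layer[node]][d] += 1
    return distribution_from_counts({l: (c["up"], c["down"]) for l, c in counts.items()})


def distribution_from_counts(per_layer: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Build the distribution table from explicit (up, down) counts per layer."""
    rows = []
    total = sum(u + d for u, d in per_layer.values())
    for layer in LAYERS:
        u, d = per_layer.get(layer, (0, 0))
        pct = round_half_up(100.0 * (u + d) / total, 1) if total else 0.0
        rows.append({"layer": layer, "up": u, "down": d, "total_pct": pct})
    rows.append({
        "layer": "total",
        "up": sum(u for u, _ in per_layer.values()),
        "down": sum(d for _, d in per_layer.values()),
        "total_pct": float(total),
    })
    return pd.DataFrame(rows).set_index("layer")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_localization_tsv(path, label_map: dict[str, str] | None = None) -> LocalizationMap:
    """2-column TSV: gene, semicolon-separated localization labels."""
    records: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("gene\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            records[parts[0]] = [s for s in parts[1].split(";") if s]
    return LocalizationMap(records=records, label_map=label_map or dict(DEFAULT_LABEL_MAP))


def write_localization_tsv(locmap: LocalizationMap, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tlocalizations\n")
        for gene in sorted(locmap.records):
            fh.write(f"{gene}\t{';'.join(locmap.records[gene])}\n")


def write_node_attributes_tsv(layered: LayeredInteractome, directions: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tlayer\tprovenance\tdirection\n")
        for node in sorted(layered.network.nodes):
            fh.write(
                f"{node}\t{layered.layer[node]}\t{layered.provenance[node]}"
                f"\t{directions.get(node, '')}\n"
            )


def write_layered_graphml(layered: LayeredInteractome, directions: dict[str, str], path) -> None:
    """GraphML with layer attribute and a tiered layout (PM top, nucleus bottom)."""
    tier_y = {"plasma_membrane": 0.0, "cytoplasm": 1.0, "nucleus": 2.0}
    g = nx.Graph()
    for layer in LAYERS:
        members = layered.nodes_in_layer(layer)
        for x, node in enumerate(members):
            g.add_node(
                node,
                layer=layer,
                provenance=layered.provenance[node],
                direction=directions.get(node, ""),
                x=float(x),
                y=tier_y[layer],
            )
    g.add_edges_from(
        sorted((min(a, b), max(a, b), d) for a, b, d in layered.network.edges(data=True))
    )
    nx.write_graphml(g, path)
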