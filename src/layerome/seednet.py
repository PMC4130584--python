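"""Seed-gene neighborhood extraction from the interactome.

Given a set of seed genes (e.g. the genes carrying an annotation of
interest), the subnetwork of interest is the induced subgraph over the
seeds and every non-seed node directly adjacent to at least one seed.
Members are ranked by ``seed_degree`` — how many distinct seeds they touch
— and split into a core tier (adjacent to every seed) and a peripheral
tier. Only direct (1-hop) interactions are considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class SeedSubnetwork:
    seeds: tuple[str, ...]                # seeds actually present in the network
    members: tuple[str, ...]              # sorted by (-seed_degree, gene id)
    seed_degree: dict[str, int]
    tier: dict[str, str]                  # member -> "core" | "peripheral"
    graph: nx.Graph                       # induced over seeds ∪ members

    @property
    def core(self) -> list[str]:
        return [m for m in self.members if self.tier[m] == "core"]


def extract_seed_network(network: nx.Graph, seeds) -> SeedSubnetwork:
    """1-hop neighborhood of the seeds with per-member seed counts.

    Seeds absent from the network are dropped with a warning; if none is
    present an error is raised. A member is ``core`` when adjacent to every
    present seed, ``peripheral`` otherwise.
    """
    requested = sorted(set(seeds))
    present = [s for s in requested if s in network]
    absent = [s for s in requested if s not in network]
    if absent:
        logger.warning("seeds not in network, dropped: %s", absent)
    if not present:
        raise ValueError(f"no seed present in the network: {requested}")

    seed_degree: dict[str, int] = {}
    for s in present:
        for nb in network.neighbors(s):
            if nb in present:
                continue
            seed_degree[nb] = seed_degree.get(nb, 0) + 1
    members = sorted(seed_degree, key=lambda g: (-seed_degree[g], g))
    tier = {m: "core" if seed_degree[m] == len(present) else "peripheral" for m in members}
    sub = network.subgraph([*present, *members]).copy()
    logger.info(
        "seed network: %d seeds, %d members (%d core)",
        len(present), len(members), sum(1 for t in tier.values() if t == "core"),
    )
    return SeedSubnetwork(
        seeds=tuple(present),
        members=tuple(members),
        seed_degree=seed_degree,
        tier=tier,
        graph=sub,
    )


def seeds_from_term(catalog, term_id: str, layered, layer: str) -> list[str]:
    """Seeds = the layer's network genes annotated to ``term_id``."""
    if term_id not in catalog:
        raise KeyError(f"term {term_id!r} not in catalog")
    layer_genes = set(layered.nodes_in_layer(layer))
    return sorted(catalog[term_id].genes & layer_genes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_seednet_tsv(subnet: SeedSubnetwork, directions: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tseed_degree\ttier\tdirection\n")
        for s in subnet.seeds:
            fh.write(f"{s}\t\tseed\t{directions.get(s, '')}\n")
        for m in subnet.members:
            fh.write(f"{m}\t{subnet.seed_degree[m]}\t{subnet.tier[m]}\t{directions.get(m, '')}\n")


def write_seednet_graphml(subnet: SeedSubnetwork, directions: dict[str, str], path) -> None:
    """GraphML with concentric-tier coordinates: seeds center, core ring, periphery."""
    import math

    g = nx.Graph()
    rings = {"seed": (list(subnet.seeds), 0.0), "core": (subnet.core, 1.0),
             "peripheral": ([m for m in subnet.members if subnet.tier[m] == "peripheral"], 2.0)}
    for tier_name, (nodes, radius) in rings.items():
        for i, node in enumerate(nodes):
            angle = 2 * math.pi * i / max(len(nodes), 1)
            g.add_node(
                node,
                tier=tier_name,
                seed_degree=subnet.seed_degree.get(node, len(subnet.seeds)),
                direction=directions.get(node, ""),
                x=radius * math.cos(angle),
                y=radius * math.sin(angle),
            )
    g.add_edges_from(
        sorted((min(a, b), max(a, b), d) for a, b, d in subnet.graph.edges(data=True))
    )
    nx.write_graphml(g, path)
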