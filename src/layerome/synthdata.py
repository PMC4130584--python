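"""Synthetic benchmark inputs with planted ground truth.

Emulates the four inputs of the layered-interactome analysis without any
external download: a two-condition expression matrix with planted
differential genes, a weighted functional-coupling network with planted
dense modules, a subcellular-localization table with a configurable
unannotated fraction, and a GO/KEGG-style term catalog in which chosen
terms are planted to be enriched among differential genes of one layer and
direction. The planted truth is returned alongside so every downstream
stage can be scored.

All randomness flows from ``rng_seed``; identical configs reproduce
byte-identical fixtures.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCatalog, write_gmt
from .expression import ExpressionDataset, write_expression_tsv
from .layering import LAYERS, LocalizationMap, write_localization_tsv
from .netbuild import write_edge_list

#: Raw-label synonyms per canonical layer, drawn from curated-database vocabulary.
_LAYER_SYNONYMS = {
    "plasma_membrane": ("plasma membrane", "cell membrane"),
    "cytoplasm": ("cytoplasm", "cytosol", "endoplasmic reticulum", "golgi apparatus"),
    "nucleus": ("nucleus", "nucleolus"),
}
_OTHER_LABELS = ("mitochondrion", "extracellular")


@dataclass(frozen=True)
class PlantedTerm:
    """A catalog term planted to be enriched in one layer and direction."""

    layer: str
    direction: str
    term_size: int
    signal_genes: int

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up or down, got {self.direction!r}")
        if not 1 <= self.signal_genes <= self.term_size:
            raise ValueError("need 1 <= signal_genes <= term_size")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic benchmark.

    ``effect_size`` is the condition mean shift in units of the within-group
    standard deviation ``noise_sd``; ``up_fraction`` is the share of
    differential genes that are up (higher in group A, the recurrent-like
    reference).
    """

    n_genes: int = 1000
    n_per_group: int = 6
    de_fraction: float = 0.1
    effect_size: float = 3.0
    up_fraction: float = 0.5
    layer_proportions: tuple[float, float, float] = (0.34, 0.33, 0.33)
    unannotated_fraction: float = 0.1
    n_terms: int = 60
    planted_terms: tuple[PlantedTerm, ...] = (
        PlantedTerm(layer="cytoplasm", direction="up", term_size=8, signal_genes=7),
    )
    edge_density_background: float = 0.01
    module_edge_density: float = 0.9
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "up_fraction", "unannotated_fraction",
                     "edge_density_background", "module_edge_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.layer_proportions) != 3 or any(not 0 <= p <= 1 for p in self.layer_proportions):
            raise ValueError("layer_proportions must be three fractions")
        if abs(sum(self.layer_proportions) - 1.0) > 1e-9:
            raise ValueError("layer_proportions must sum to 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (t-test needs a variance estimate)")
        if self.n_terms < len(self.planted_terms):
            raise ValueError("n_terms must cover the planted terms")
        self.planted_terms = tuple(
            t if isinstance(t, PlantedTerm) else PlantedTerm(**t) for t in self.planted_terms
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: what downstream stages are expected to recover."""

    de_genes: dict[str, str]                       # gene -> up | down
    planted_term_ids: dict[str, dict[str, str]]    # term -> {layer, direction}
    planted_module_edges: list[tuple[str, str]]
    layer_truth: dict[str, str]                    # gene -> layer


class SyntheticBundle(NamedTuple):
    dataset: ExpressionDataset
    network: nx.Graph
    locmap: LocalizationMap
    catalog: GeneSetCatalog
    truth: SyntheticTruth


def simulate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the four inputs plus the planted truth for one config.

    Expression values are per-gene baseline + condition shift
    (effect_size * noise_sd for differential genes, signed by direction)
    + i.i.d. Gaussian noise. Planted terms draw their signal genes from
    differential genes of the requested layer and direction, and the
    remaining members from non-differential genes of the same layer (so
    the term's modal true layer is the planted layer). The network is an
    Erdős–Rényi background plus dense modules over each planted term's
    signal genes, with isolated nodes connected to a module so the largest
    component is non-trivial.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    genes = [f"G{i + 1:06d}" for i in range(n)]

    layer_idx = rng.choice(3, size=n, p=np.asarray(config.layer_proportions, float))
    layer_truth = {g: LAYERS[k] for g, k in zip(genes, layer_idx)}

    n_de = int(round(n * config.de_fraction))
    de_order = rng.permutation(n)[:n_de]
    n_up = int(round(n_de * config.up_fraction))
    de_genes = {genes[i]: ("up" if rank < n_up else "down")
                for rank, i in enumerate(de_order)}

    dataset = _simulate_expression(config, genes, de_genes, rng)
    catalog, planted_map, planted_members = _simulate_catalog(
        config, genes, de_genes, layer_truth, rng
    )
    network, module_edges = _simulate_network(config, genes, planted_members, rng)
    locmap = _simulate_localization(config, genes, layer_truth, rng)

    truth = SyntheticTruth(
        de_genes=de_genes,
        planted_term_ids=planted_map,
        planted_module_edges=module_edges,
        layer_truth=layer_truth,
    )
    return SyntheticBundle(dataset, network, locmap, catalog, truth)


def _simulate_expression(config, genes, de_genes, rng) -> ExpressionDataset:
    m = config.n_per_group
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    shift = np.zeros(len(genes))
    for i, g in enumerate(genes):
        d = de_genes.get(g)
        if d:
            shift[i] = config.effect_size * config.noise_sd * (1 if d == "up" else -1)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * m))
    values[:, :m] += shift[:, None]  # group A (recurrent-like reference) carries the shift
    sample_ids = [f"A{i + 1:02d}" for i in range(m)] + [f"B{i + 1:02d}" for i in range(m)]
    condition = pd.Series(["groupA"] * m + ["groupB"] * m, index=sample_ids)
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ExpressionDataset(values=frame, condition=condition, group_a="groupA")


def _simulate_catalog(config, genes, de_genes, layer_truth, rng):
    """Planted terms first, then random filler terms up to ``n_terms``."""
    used_signal: set[str] = set()
    planted_map: dict[str, dict[str, str]] = {}
    planted_members: list[list[str]] = []
    terms: list[GeneSet] = []

    for k, spec in enumerate(config.planted_terms, start=1):
        pool = sorted(
            g for g, d in de_genes.items()
            if d == spec.direction and layer_truth[g] == spec.layer and g not in used_signal
        )
        if len(pool) < spec.signal_genes:
            raise ValueError(
                f"planted term {k}: needs {spec.signal_genes} {spec.direction} genes in "
                f"{spec.layer}, only {len(pool)} available"
            )
        signal = [pool[i] for i in rng.choice(len(pool), spec.signal_genes, replace=False)]
        used_signal.update(signal)
        filler_pool = sorted(
            g for g in genes
            if g not in de_genes and layer_truth[g] == spec.layer and g not in signal
        )
        n_filler = spec.term_size - spec.signal_genes
        if len(filler_pool) < n_filler:
            raise ValueError(f"planted term {k}: not enough {spec.layer} filler genes")
        filler = [filler_pool[i] for i in rng.choice(len(filler_pool), n_filler, replace=False)]
        members = sorted([*signal, *filler])
        term_id = f"GO:9{k:06d}"
        terms.append(GeneSet(
            term_id=term_id,
            term_name=f"planted {spec.direction} {spec.layer} process {k}",
            genes=frozenset(members),
        ))
        planted_map[term_id] = {"layer": spec.layer, "direction": spec.direction}
        planted_members.append(members)

    n_random = config.n_terms - len(config.planted_terms)
    for k in range(1, n_random + 1):
        size = int(rng.integers(5, 26))
        members = [genes[i] for i in rng.choice(len(genes), size, replace=False)]
        if k % 5 == 0:
            term_id, name = f"KEGG:{k:05d}", f"random pathway {k}"
        else:
            term_id, name = f"GO:{k:07d}", f"random process {k}"
        terms.append(GeneSet(term_id=term_id, term_name=name, genes=frozenset(members)))
    return GeneSetCatalog(terms=terms), planted_map, planted_members


def _simulate_network(config, genes, planted_members, rng):
    """ER background + dense modules over planted signal genes.

    Isolated nodes are attached to a random module gene (or any random
    gene when no module exists) so the graph has no degree-0 nodes.
    O(n^2) pair sampling; fine at benchmark scale.
    """
    n = len(genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < config.edge_density_background
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(genes[i], genes[j], confidence=float(rng.uniform(0.1, 1.0)))

    module_edges: list[tuple[str, str]] = []
    for members in planted_members:
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                if rng.random() < config.module_edge_density:
                    a, b = members[a_i], members[b_i]
                    g.add_edge(a, b, confidence=float(rng.uniform(0.8, 1.0)))
                    module_edges.append((a, b))

    anchors = sorted({m for members in planted_members for m in members}) or genes
    for node in genes:
        if g.degree(node) == 0:
            target = anchors[int(rng.integers(len(anchors)))]
            if target == node:
                target = genes[(genes.index(node) + 1) % n]
            g.add_edge(node, target, confidence=float(rng.uniform(0.5, 1.0)))
    return g, module_edges


def _simulate_localization(config, genes, layer_truth, rng) -> LocalizationMap:
    records: dict[str, list[str]] = {}
    for g in genes:
        if rng.random() < config.unannotated_fraction:
            continue
        synonyms = _LAYER_SYNONYMS[layer_truth[g]]
        labels = [synonyms[int(rng.integers(len(synonyms)))]]
        if rng.random() < 0.1:  # occasional extra non-layer compartment
            labels.append(_OTHER_LABELS[int(rng.integers(len(_OTHER_LABELS)))])
        records[g] = labels
    return LocalizationMap(records=records)


# ---------------------------------------------------------------------------
# Fixture serialization
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixtures(bundle: SyntheticBundle, directory) -> dict:
    """Write the bundle as plain-text fixtures; return a hashed manifest.

    Files: expression.tsv, network.tsv (edge list), localization.tsv,
    catalog.gmt, truth.json, manifest.json.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "network": os.path.join(directory, "network.tsv"),
        "localization": os.path.join(directory, "localization.tsv"),
        "catalog": os.path.join(directory, "catalog.gmt"),
        "truth": os.path.join(directory, "truth.json"),
    }
    try:
        write_expression_tsv(bundle.dataset, paths["expression"])
        write_edge_list(bundle.network.edges(data="confidence"), paths["network"])
        write_localization_tsv(bundle.locmap, paths["localization"])
        write_gmt(bundle.catalog, paths["catalog"])
        with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump({
                "de_genes": bundle.truth.de_genes,
                "planted_term_ids": bundle.truth.planted_term_ids,
                "planted_module_edges": [list(e) for e in bundle.truth.planted_module_edges],
                "layer_truth": bundle.truth.layer_truth,
            }, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture {exc.filename}: {exc}") from exc

    manifest = {
        "files": {name: {"path": os.path.basename(p), "sha256": _sha256(p)}
                  for name, p in paths.items()},
    }
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
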