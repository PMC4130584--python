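"""End-to-end orchestration: expression -> network -> layers -> terms -> groups.

`run_analysis` is the pure in-memory pipeline used by tests and
simulations; `run_pipeline` wraps it with file input/output, a structured
log and a JSON report. Identical config + inputs (including the seed)
produce byte-identical reports: stage timings go to the log only, every
tie-break downstream is deterministic, and the report is serialized with
sorted keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import tomllib
from dataclasses import dataclass, field

import networkx as nx

from . import enrichment as enr
from . import grouping, layering, netbuild, seednet, synthdata
from .expression import (
    ExpressionDataset,
    cluster_directions,
    read_expression_tsv,
    select_de_genes,
    write_de_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """All tunable thresholds of the analysis, with their defaults."""

    alpha_de: float = 0.05
    alpha_terms: float = 0.05
    min_confidence: float = 0.0
    min_component_size: int = 5
    keep_largest_only: bool = True
    layer_priority: tuple[str, str, str] = layering.DEFAULT_PRIORITY
    kappa_threshold: float = grouping.DEFAULT_KAPPA_THRESHOLD
    share_threshold: float = grouping.DEFAULT_SHARE_THRESHOLD
    pct_up_threshold: float = grouping.DEFAULT_PCT_UP_THRESHOLD
    min_hits: int = 2
    ease: bool = False
    background: str = "expression"  # "expression" (all assayed genes) | "network"


@dataclass
class PipelineConfig:
    """One run: either a synthetic config or four input paths, plus params."""

    params: AnalysisParams = field(default_factory=AnalysisParams)
    synthetic: synthdata.SyntheticConfig | None = None
    inputs: dict[str, str] | None = None           # expression/network/localization/catalog
    seeds: dict | None = None                      # {"genes": [...]} or {"term": id, "layer": l}
    output_dir: str = "layerome_out"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        params = AnalysisParams(**raw.get("params", {}))
        if isinstance(params.layer_priority, list):
            params.layer_priority = tuple(params.layer_priority)
        synth = None
        if "synthetic" in raw:
            s = dict(raw["synthetic"])
            if "layer_proportions" in s:
                s["layer_proportions"] = tuple(s["layer_proportions"])
            if "planted_terms" in s:
                s["planted_terms"] = tuple(
                    synthdata.PlantedTerm(**t) for t in s["planted_terms"]
                )
            synth = synthdata.SyntheticConfig(**s)
        inputs = raw.get("inputs")
        if synth is None and inputs is None:
            raise ValueError(f"{path}: needs a [synthetic] or [inputs] section")
        if inputs is not None:
            for key in ("expression", "network", "localization", "catalog"):
                if key not in inputs:
                    raise ValueError(f"{path}: [inputs] missing {key!r}")
        return cls(
            params=params,
            synthetic=synth,
            inputs=inputs,
            seeds=raw.get("seeds"),
            output_dir=raw.get("output", {}).get("directory", "layerome_out"),
        )


@dataclass
class AnalysisResult:
    de_result: object
    network_initial: nx.Graph
    network: nx.Graph
    layered: layering.LayeredInteractome
    distribution: object                       # DataFrame from layer_distribution
    enriched: dict[str, list[enr.EnrichmentResult]]
    groups: dict[str, list[grouping.AnnotationGroup]]
    kappa_graphs: dict[str, nx.Graph]
    seed_network: seednet.SeedSubnetwork | None = None

    @property
    def directions(self) -> dict[str, str]:
        return self.de_result.direction_map


def run_analysis(
    dataset: ExpressionDataset,
    edges,
    locmap: layering.LocalizationMap,
    catalog: enr.GeneSetCatalog,
    params: AnalysisParams = AnalysisParams(),
    seeds: dict | None = None,
) -> AnalysisResult:
    """Run every stage in order on in-memory inputs.

    ``edges`` is an iterable of (gene_a, gene_b, confidence) triples, e.g.
    ``graph.edges(data="confidence")``. Stage failures raise with the stage
    name prefixed.
    """
    stage = "expression"
    try:
        de = select_de_genes(dataset, params.alpha_de)
        de = cluster_directions(dataset, de)
        directions = de.direction_map
        directed = de.genes_with_direction("up", "down")

        stage = "netbuild"
        net0 = netbuild.build_network(edges, directed, params.min_confidence, directions)
        net = netbuild.filter_components(
            net0, params.min_component_size, params.keep_largest_only
        )

        stage = "layering"
        layered = layering.assign_layers(net, locmap, params.layer_priority)
        distribution = layering.layer_distribution(layered, directions)

        stage = "enrichment"
        background = (
            dataset.gene_ids if params.background == "expression" else sorted(net.nodes)
        )
        enriched, groups, kgraphs = {}, {}, {}
        for layer in layering.LAYERS:
            enriched[layer] = enr.enrich_layer(
                layered, layer, catalog, background, directions,
                alpha=params.alpha_terms, min_hits=params.min_hits, ease=params.ease,
            )

        stage = "grouping"
        for layer in layering.LAYERS:
            groups[layer], kgraphs[layer] = grouping.group_layer(
                enriched[layer], layered.nodes_in_layer(layer), directions, layer,
                params.kappa_threshold, params.share_threshold, params.pct_up_threshold,
            )

        seed_sub = None
        if seeds:
            stage = "seednet"
            if "genes" in seeds:
                seed_ids = list(seeds["genes"])
            else:
                seed_ids = seednet.seeds_from_term(
                    catalog, seeds["term"], layered, seeds.get("layer", "cytoplasm")
                )
            seed_sub = seednet.extract_seed_network(net, seed_ids)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return AnalysisResult(
        de_result=de,
        network_initial=net0,
        network=net,
        layered=layered,
        distribution=distribution,
        enriched=enriched,
        groups=groups,
        kappa_graphs=kgraphs,
        seed_network=seed_sub,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def build_report(
    result: AnalysisResult,
    params: AnalysisParams,
    config_echo: dict,
    input_hashes: dict[str, str],
) -> dict:
    """Assemble the JSON-serializable run report."""
    dist = result.distribution
    directions = result.directions
    report = {
        "config": config_echo,
        "input_hashes": input_hashes,
        "direction_clustering": "two_medoid_correlation",  # CLICK substitute
        "enrichment_variant": "EASE" if params.ease else "hypergeometric",
        "de_counts": result.de_result.counts(),
        "network": {
            "initial_nodes": result.network_initial.number_of_nodes(),
            "initial_edges": result.network_initial.number_of_edges(),
            "filtered_nodes": result.network.number_of_nodes(),
            "filtered_edges": result.network.number_of_edges(),
        },
        "layer_distribution": [
            {"layer": layer, "up": int(row["up"]), "down": int(row["down"]),
             "total_pct": float(row["total_pct"])}
            for layer, row in dist.iterrows()
        ],
        "enriched_terms": {
            layer: [
                {"term_id": r.term_id, "name": r.term_name, "x": r.x, "K": r.K,
                 "n": r.n, "N": r.N, "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
                 "pct_up": r.pct_up}
                for r in results
            ]
            for layer, results in result.enriched.items()
        },
        "groups": {
            layer: [
                {"members": list(g.members), "label_terms": list(g.label_terms),
                 "direction": g.direction, "leading_p_bonferroni": g.leading_p_bonferroni}
                for g in gs
            ]
            for layer, gs in result.groups.items()
        },
    }
    if result.seed_network is not None:
        sn = result.seed_network
        report["seed_network"] = {
            "seeds": list(sn.seeds),
            "members": [
                {"gene": m, "seed_degree": sn.seed_degree[m], "tier": sn.tier[m],
                 "direction": directions.get(m, "")}
                for m in sn.members
            ],
        }
    return report


def render_table1(report_or_distribution) -> str:
    """Format the per-layer node distribution like the published table.

    Rows: three layers then Total; columns: up-regulated count,
    down-regulated count, and total percentage (half-up, one decimal). The
    Total row's last cell is the grand node total.
    """
    if isinstance(report_or_distribution, dict):
        rows = report_or_distribution["layer_distribution"]
    else:
        rows = [
            {"layer": layer, "up": int(r["up"]), "down": int(r["down"]),
             "total_pct": float(r["total_pct"])}
            for layer, r in report_or_distribution.iterrows()
        ]
    pretty = {"plasma_membrane": "Plasma membrane", "cytoplasm": "Cytoplasm",
              "nucleus": "Nucleus", "total": "Total"}
    lines = ["Localization\tUp-regulated\tDown-regulated\tTotal%"]
    for row in rows:
        pct = row["total_pct"]
        cell = str(int(pct)) if row["layer"] == "total" else f"{pct:.1f}"
        lines.append(f"{pretty[row['layer']]}\t{row['up']}\t{row['down']}\t{cell}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# File-backed run
# ---------------------------------------------------------------------------

def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    echo = {"params": dataclasses.asdict(config.params), "output_dir": config.output_dir}
    echo["params"]["layer_priority"] = list(config.params.layer_priority)
    if config.synthetic is not None:
        s = dataclasses.asdict(config.synthetic)
        s["layer_proportions"] = list(s["layer_proportions"])
        s["planted_terms"] = [dataclasses.asdict(t) for t in config.synthetic.planted_terms]
        echo["synthetic"] = s
    if config.inputs is not None:
        echo["inputs"] = dict(config.inputs)
    if config.seeds is not None:
        echo["seeds"] = dict(config.seeds)
    return echo


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from a config; write artifacts; return the report."""
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    t0 = time.perf_counter()

    if config.synthetic is not None:
        bundle = synthdata.simulate_dataset(config.synthetic)
        manifest = synthdata.write_fixtures(bundle, os.path.join(outdir, "inputs"))
        dataset, graph, locmap, catalog, _ = bundle
        edges = list(graph.edges(data="confidence"))
        input_hashes = {k: v["sha256"] for k, v in manifest["files"].items()}
    else:
        paths = config.inputs
        dataset = read_expression_tsv(paths["expression"])
        edges = netbuild.read_edge_list(paths["network"])
        locmap = layering.read_localization_tsv(paths["localization"])
        catalog = enr.read_gmt(paths["catalog"])
        input_hashes = {k: _hash_file(p) for k, p in paths.items()}
    logger.info("inputs ready in %.2fs", time.perf_counter() - t0)

    result = run_analysis(dataset, edges, locmap, catalog, config.params, config.seeds)
    logger.info("analysis done in %.2fs", time.perf_counter() - t0)

    directions = result.directions
    write_de_tsv(result.de_result, os.path.join(outdir, "de_genes.tsv"))
    netbuild.write_edge_list(result.network, os.path.join(outdir, "network.tsv"))
    netbuild.write_sif(result.network, os.path.join(outdir, "network.sif"))
    netbuild.write_graphml(result.network, os.path.join(outdir, "network.graphml"))
    layering.write_node_attributes_tsv(
        result.layered, directions, os.path.join(outdir, "layers.tsv")
    )
    layering.write_layered_graphml(
        result.layered, directions, os.path.join(outdir, "layered.graphml")
    )
    for layer in layering.LAYERS:
        enr.write_enrichment_tsv(
            result.enriched[layer], os.path.join(outdir, f"enrichment_{layer}.tsv")
        )
        grouping.write_kappa_graphml(
            result.kappa_graphs[layer], result.enriched[layer],
            os.path.join(outdir, f"kappa_{layer}.graphml"),
        )
    all_groups = [g for layer in layering.LAYERS for g in result.groups[layer]]
    grouping.write_groups_tsv(all_groups, os.path.join(outdir, "groups.tsv"))
    if result.seed_network is not None:
        seednet.write_seednet_tsv(
            result.seed_network, directions, os.path.join(outdir, "seed_network.tsv")
        )
        seednet.write_seednet_graphml(
            result.seed_network, directions, os.path.join(outdir, "seed_network.graphml")
        )

    report = build_report(result, config.params, _config_echo(config), input_hashes)
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "table1.tsv"), "w", encoding="utf-8", newline="\n") as fh:
        fh.write(render_table1(report) + "\n")
    logger.info("pipeline complete in %.2fs; outputs in %s", time.perf_counter() - t0, outdir)
    return report
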