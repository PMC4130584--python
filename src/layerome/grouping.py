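"""Kappa-similarity grouping of enriched terms with direction labels.

Significant terms of one layer are compared by Cohen's chance-corrected
kappa over their hit-gene memberships (binary membership vectors against
the layer's differential genes as the reference set). Terms with kappa
above a threshold are linked; groups start from closed kappa-neighborhoods
and are merged iteratively while any two groups share at least a fraction
of the smaller group's terms. Each final group is labeled by its most
significant up- and/or down-regulated member term, and the pooled hit genes
decide whether the group as a whole is up, down or mixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

DEFAULT_KAPPA_THRESHOLD = 0.3
DEFAULT_SHARE_THRESHOLD = 0.5
DEFAULT_PCT_UP_THRESHOLD = 0.6


def kappa(term_a_genes, term_b_genes, reference) -> float:
    """Cohen's kappa between two binary memberships over ``reference``.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|, d = N−a−b−c:
    po = (a+d)/N, pe = ((a+b)(a+c) + (c+d)(b+d))/N², kappa = (po−pe)/(1−pe).
    If pe = 1 (both memberships constant) the convention is 1 for identical
    memberships and 0 otherwise.
    """
    ref = set(reference)
    A, B = set(term_a_genes), set(term_b_genes)
    if not A <= ref or not B <= ref:
        raise ValueError("term gene sets must be subsets of the reference")
    N = len(ref)
    if N < 2:
        raise ValueError("reference must contain at least 2 genes")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if math.isclose(pe, 1.0):
        return 1.0 if A == B else 0.0
    return (po - pe) / (1.0 - pe)


def build_kappa_graph(
    enriched: list[EnrichmentResult],
    reference,
    threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> nx.Graph:
    """Term-term graph with an edge wherever kappa > threshold (strict).

    Memberships are the hit-gene sets (term ∩ layer differential genes);
    the reference is the layer's differential gene set. The reference size
    is stored as the graph attribute ``reference_size``.
    """
    if not -1 <= threshold <= 1:
        raise ValueError("threshold must be in [-1, 1]")
    ref = set(reference)
    g = nx.Graph(reference_size=len(ref))
    hits = {r.term_id: set(r.hit_genes) for r in enriched}
    for r in enriched:
        g.add_node(r.term_id)
    ids = sorted(hits)
    for i, ta in enumerate(ids):
        for tb in ids[i + 1:]:
            k = kappa(hits[ta], hits[tb], ref)
            if k > threshold:
                g.add_edge(ta, tb, kappa=k)
    return g


@dataclass
class AnnotationGroup:
    """A merged set of enriched terms with a leading label and direction."""

    layer: str
    members: tuple[str, ...]
    label_terms: tuple[str, ...] = ()
    direction: str = "mixed"
    leading_p_bonferroni: float = float("nan")


def _share(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def merge_groups(
    kgraph: nx.Graph,
    share_threshold: float = DEFAULT_SHARE_THRESHOLD,
) -> list[frozenset[str]]:
    """Iteratively merge closed kappa-neighborhoods to a fixed point.

    Initial groups are the closed neighborhoods (term plus its kappa
    neighbors) of every term with at least one edge; isolated terms form
    singleton groups. While any two groups share >= ``share_threshold`` of
    the smaller group's terms, the pair with the highest sharing fraction
    (ties by the lexicographically smallest combined member tuple) is
    merged. The group count strictly decreases, so a fixed point is
    guaranteed. Returns sorted member sets, in order of smallest member id.
    """
    if not 0 < share_threshold <= 1:
        raise ValueError("share_threshold must be in (0, 1]")
    groups: list[frozenset[str]] = []
    for term in sorted(kgraph.nodes):
        if kgraph.degree(term) > 0:
            groups.append(frozenset({term, *kgraph.neighbors(term)}))
        else:
            groups.append(frozenset({term}))
    groups = sorted(set(groups), key=lambda g: sorted(g))

    while True:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                s = _share(groups[i], groups[j])
                if s < share_threshold:
                    continue
                key = (-s, tuple(sorted(groups[i] | groups[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        groups = sorted(set(groups), key=lambda g: sorted(g))
    return groups


def label_and_direct(
    members,
    enriched: list[EnrichmentResult],
    directions: dict[str, str],
    layer: str,
    pct_up_threshold: float = DEFAULT_PCT_UP_THRESHOLD,
) -> AnnotationGroup:
    """Label a group by its most significant up/down terms and type it.

    A member term is up if its pct_up >= threshold, down if <= 1−threshold,
    else mixed. The label terms are the minimum-p_bonferroni up term and/or
    down term (both when both exist; the overall minimum-p member when
    neither exists). The group direction applies the same threshold to the
    pooled (union) hit genes of all members.
    """
    if not 0.5 < pct_up_threshold <= 1:
        raise ValueError("pct_up_threshold must be in (0.5, 1]")
    members = tuple(sorted(members))
    by_id = {r.term_id: r for r in enriched}
    missing = [t for t in members if t not in by_id]
    if missing:
        raise ValueError(f"group members absent from enrichment results: {missing}")

    def term_type(r: EnrichmentResult) -> str:
        if r.pct_up >= pct_up_threshold:
            return "up"
        if r.pct_up <= 1 - pct_up_threshold:
            return "down"
        return "mixed"

    labels = []
    for want in ("up", "down"):
        cands = [by_id[t] for t in members if term_type(by_id[t]) == want]
        if cands:
            labels.append(min(cands, key=lambda r: (r.p_bonferroni, r.term_id)).term_id)
    if not labels:  # all members mixed: fall back to the most significant one
        labels = [min((by_id[t] for t in members),
                      key=lambda r: (r.p_bonferroni, r.term_id)).term_id]

    pooled = set()
    for t in members:
        pooled |= set(by_id[t].hit_genes)
    n_up = sum(1 for g in pooled if directions.get(g) == "up")
    frac_up = n_up / len(pooled) if pooled else 0.0
    if frac_up >= pct_up_threshold:
        direction = "up"
    elif frac_up <= 1 - pct_up_threshold:
        direction = "down"
    else:
        direction = "mixed"

    return AnnotationGroup(
        layer=layer,
        members=members,
        label_terms=tuple(labels),
        direction=direction,
        leading_p_bonferroni=min(by_id[t].p_bonferroni for t in members),
    )


def group_layer(
    enriched: list[EnrichmentResult],
    reference,
    directions: dict[str, str],
    layer: str,
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD,
    share_threshold: float = DEFAULT_SHARE_THRESHOLD,
    pct_up_threshold: float = DEFAULT_PCT_UP_THRESHOLD,
) -> tuple[list[AnnotationGroup], nx.Graph]:
    """Full grouping for one layer: kappa graph, merge, label."""
    kgraph = build_kappa_graph(enriched, reference, kappa_threshold)
    member_sets = merge_groups(kgraph, share_threshold)
    groups = [
        label_and_direct(m, enriched, directions, layer, pct_up_threshold)
        for m in member_sets
    ]
    logger.info("grouping %s: %d terms -> %d groups", layer, len(enriched), len(groups))
    return groups, kgraph


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_groups_tsv(groups: list[AnnotationGroup], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("group_id\tlayer\tdirection\tlabel_terms\tmembers\tleading_p_bonferroni\n")
        for i, g in enumerate(groups, start=1):
            fh.write(
                f"{i}\t{g.layer}\t{g.direction}\t{';'.join(g.label_terms)}"
                f"\t{';'.join(g.members)}\t{g.leading_p_bonferroni:.6g}\n"
            )


def write_kappa_graphml(
    kgraph: nx.Graph,
    enriched: list[EnrichmentResult],
    path,
    p_display_range: tuple[float, float] = (5e-2, 5e-6),
) -> None:
    """Kappa graph with node size mapped to −log10(p_bonferroni).

    p-values are clipped to the display range before the log transform so
    node sizes span a bounded scale.
    """
    hi, lo = max(p_display_range), min(p_display_range)
    g = nx.Graph()
    for r in sorted(enriched, key=lambda r: r.term_id):
        if r.term_id not in kgraph:
            continue
        p = min(max(r.p_bonferroni, lo), hi)
        g.add_node(r.term_id, name=r.term_name, p_bonferroni=r.p_bonferroni,
                   size=-math.log10(p), pct_up=r.pct_up)
    g.add_edges_from(sorted((min(a, b), max(a, b), d) for a, b, d in kgraph.edges(data=True)))
    nx.write_graphml(g, path)
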