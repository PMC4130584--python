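"""Per-layer gene-set over-representation with Bonferroni control.

Each layer's differential genes are tested against a GO/KEGG-style term
catalog with the hypergeometric upper tail (optionally the conservative
EASE-style variant that discounts one hit). The Bonferroni factor is the
number of terms actually tested in that layer (terms reaching ``min_hits``
overlap), matching the terms-tested semantics of the correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]

    @property
    def source(self) -> str:
        if self.term_id.startswith("GO"):
            return "GO_BP"
        if self.term_id.upper().startswith("KEGG"):
            return "KEGG"
        return "other"


@dataclass
class GeneSetCatalog:
    """Ordered term catalog with unique ids and non-empty gene sets."""

    terms: list[GeneSet]
    _by_id: dict[str, GeneSet] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term ids in catalog")
        if any(not t.genes for t in self.terms):
            raise ValueError("catalog contains an empty gene set")
        self._by_id = {t.term_id: t for t in self.terms}

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._by_id[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id


def hypergeometric_pvalue(x: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    With ``ease=True`` the EASE-style conservative score P(X >= x-1) is
    returned instead (one hit discounted; x=0 or 1 then gives p=1).
    """
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"need 0 <= x <= min(K, n); got x={x}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    if ease:
        x = max(x - 1, 0)
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise adjusted p: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


@dataclass
class EnrichmentResult:
    """Over-representation of one term in one layer's differential genes."""

    term_id: str
    term_name: str
    source: str
    layer: str
    x: int           # hits: term ∩ layer genes
    K: int           # term size within the background
    n: int           # layer gene count within the background
    N: int           # background size
    p_raw: float
    p_bonferroni: float
    hit_genes: tuple[str, ...]
    pct_up: float    # fraction of hit genes labeled up


def enrich_layer(
    layered,
    layer: str,
    catalog: GeneSetCatalog,
    background,
    directions: dict[str, str],
    alpha: float = 0.05,
    min_hits: int = 2,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Significant terms for one layer, Bonferroni-controlled.

    Terms whose overlap with the layer's genes reaches ``min_hits`` are
    tested (and only they count toward the Bonferroni factor m). Returns
    terms with p_bonferroni < alpha sorted by (p_bonferroni, term_id).
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    background = set(background)
    layer_genes = set(layered.nodes_in_layer(layer))
    if not layer_genes:
        logger.warning("layer %s has no genes; empty enrichment", layer)
        return []
    if not layer_genes <= background:
        raise ValueError("layer genes must be a subset of the background")
    n = len(layer_genes)
    N = len(background)

    tested = []
    for term in catalog.terms:
        term_bg = term.genes & background
        hits = sorted(term_bg & layer_genes)
        if len(hits) < min_hits:
            continue
        tested.append((term, len(term_bg), hits))
    m = len(tested)

    results = []
    for term, K, hits in tested:
        p_raw = hypergeometric_pvalue(len(hits), K, n, N, ease=ease)
        p_adj = bonferroni(p_raw, m)
        if p_adj >= alpha:
            continue
        n_up = sum(1 for g in hits if directions.get(g) == "up")
        results.append(EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            source=term.source,
            layer=layer,
            x=len(hits), K=K, n=n, N=N,
            p_raw=p_raw, p_bonferroni=p_adj,
            hit_genes=tuple(hits),
            pct_up=n_up / len(hits),
        ))
    results.sort(key=lambda r: (r.p_bonferroni, r.term_id))
    logger.info("enrich %s: %d significant of %d tested terms (m=%d)", layer, len(results), m, m)
    return results


# ---------------------------------------------------------------------------
# I/O: GMT catalog, result TSV
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCatalog:
    """GMT: one term per line — name, description, then member genes."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            terms.append(GeneSet(term_id=parts[0], term_name=parts[1], genes=frozenset(parts[2:])))
    return GeneSetCatalog(terms=terms)


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in catalog.terms:
            fh.write("\t".join([term.term_id, term.term_name, *sorted(term.genes)]) + "\n")


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "term_id\tname\tsource\tlayer\tx\tK\tn\tN\tp_raw\tp_bonferroni\tpct_up\thit_genes\n"
        )
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.source}\t{r.layer}\t{r.x}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t{r.pct_up:.4f}"
                f"\t{';'.join(r.hit_genes)}\n"
            )
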