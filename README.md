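# layerome

Annotation grouping on the subcellular layered interactome.

`layerome` is for systems biologists who want to move from a two-condition
expression experiment to a spatially organized functional readout: which
biological processes are differentially active, and in which cellular
compartment. Starting from a gene × sample expression matrix, a weighted
functional-coupling edge list (FunCoup-style), a protein
subcellular-localization table (HPRD-style) and a GO/KEGG-style gene-set
catalog, the pipeline:

1. **Differential expression** — flags genes with a two-sided
   pooled-variance Student's t-test at raw p < α (default 0.05), then
   splits them into up- and down-regulated clusters by deterministic
   2-medoid clustering of standardized profiles under correlation distance
   (genes uncorrelated with either cluster centroid stay `unclustered` and
   are dropped downstream).
2. **Network assembly** — induces the interaction network on the directed
   differential genes, removing self-loops and duplicate edges, then drops
   components with fewer than five nodes and keeps the largest component.
3. **Layering** — places each node in the plasma-membrane, cytoplasm or
   nucleus layer from its localization records (multi-localized proteins
   resolved by a priority order); unannotated nodes inherit the majority
   layer of the nearest annotated nodes by breadth-first distance.
4. **Over-representation** — tests each catalog term against each layer's
   genes with the hypergeometric upper tail
   `P(X ≥ x), X ~ Hypergeom(N, K, n)` and Bonferroni control over the
   terms tested in that layer; keeps terms with adjusted p < 0.05.
5. **Annotation grouping** — links significant terms whose hit-gene
   memberships agree by Cohen's chance-corrected kappa
   `κ = (p_o − p_e)/(1 − p_e) > 0.3`, merges closed neighborhoods
   iteratively while two groups share ≥ 50 % of the smaller one, and
   labels each group with its most significant up- and/or down-regulated
   member term; the pooled hit genes decide the group's direction
   (up/down at ≥ 60 %, otherwise mixed).
6. **Seed networks** — extracts the 1-hop neighborhood of chosen seed
   genes from the interactome, ranking partners by how many seeds they
   touch (core = all seeds, peripheral = fewer).

A synthetic-data module generates all four inputs with planted ground
truth (differential genes with known directions, dense network modules,
layer labels, terms enriched in a chosen layer and direction), so the
whole pipeline is testable end to end without any external database.

## Worked example

```python
import layerome as L
from layerome.pipeline import render_table1

cfg = L.SyntheticConfig(rng_seed=1)          # 1,000 genes, 6 samples/group,
bundle = L.simulate_dataset(cfg)             # one planted up-cytoplasm term
res = L.run_analysis(bundle.dataset, bundle.network.edges(data="confidence"),
                     bundle.locmap, bundle.catalog)

print(res.de_result.counts())
print(render_table1(res.distribution))
for r in res.enriched["cytoplasm"]:
    print(r.term_id, r.term_name, r.x, r.K, f"{r.p_bonferroni:.3g}", r.pct_up)
for g in res.groups["cytoplasm"]:
    print(g.members, g.label_terms, g.direction, f"{g.leading_p_bonferroni:.3g}")
```

prints

```
{'total_de': 142, 'up': 76, 'down': 66, 'unclustered': 0}
Localization	Up-regulated	Down-regulated	Total%
Plasma membrane	16	13	30.9
Cytoplasm	21	10	33.0
Nucleus	14	20	36.2
Total	51	43	94
GO:9000001 planted up cytoplasm process 1 6 8 5.77e-08 1.0
('GO:9000001',) ('GO:9000001',) up 5.77e-08
```

Reading this: 142 of 1,000 genes pass the t-test filter (100 planted plus
the expected ~5 % false positives), 76 up and 66 down. After the network
filters, 94 genes remain and distribute across the three layers. In the
cytoplasm layer the planted term is recovered: 6 of its 8 members are
cytoplasm differential genes (Bonferroni p ≈ 6 × 10⁻⁸, all hits
up-regulated), and it forms a single annotation group labeled **up** —
exactly the planted truth.

The same run is available from the shell:

```sh
layerome run --config run.toml        # end-to-end, writes report.json + tables
layerome simulate --out fixtures/     # just the synthetic inputs
layerome de --expression fixtures/expression.tsv --out de.tsv
```

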