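# Methods

## The analysis model

`layerome` treats a two-condition comparison as a pipeline of five
inferential steps over four inputs: an expression matrix, a weighted
undirected interaction network, a gene → subcellular-localization map and
a flat term catalog. The guiding assumption is spatial: a protein's
functional context is constrained by its compartment, so enrichment is
assessed *per layer* (plasma membrane, cytoplasm, nucleus) of the
condition-specific interactome rather than over the whole differential
gene list.

**Differential filter.** A two-sided pooled-variance (equal-variance)
two-sample t-test per gene, df = n_A + n_B − 2, at raw p < `alpha_de`
(default 0.05). No multiplicity correction is applied at this stage;
family-wise control enters later, at the annotation-term level. The
direction reference is group A ("recurrent-like"): up means
mean(A) − mean(B) > 0. Degenerate inputs (zero pooled variance) use the
convention t = 0, p = 1 for equal means and p = 0 otherwise.

**Direction clustering.** Differential genes are split into an up and a
down cluster by 2-medoid partitioning of per-gene z-scored profiles under
correlation distance. Medoids are seeded from the two genes with the most
extreme mean difference, making the procedure deterministic; clusters are
labeled by the sign of their centroid's group contrast. A gene whose
correlation with its own cluster centroid is ≤ `corr_floor` (default 0)
is left `unclustered` and excluded from the network stage, mirroring the
occasional leftover genes of graph-based expression clustering. This
deterministic two-cluster procedure replaces a heavier probabilistic
graph-clustering algorithm whose only observable role here is the same
two-way split; the report records the substitution in its
`direction_clustering` field. Note the floor is an "at or below" rule: an
exactly orthogonal profile is dropped. (A member of a multi-gene cluster
always has positive correlation with a centroid that contains it, so the
floor only bites for genuinely discordant profiles or a raised floor.)

**Network assembly.** Edges are kept when both endpoints are directed
(up/down) differential genes and confidence ≥ `min_confidence` (default
0; the upstream database's own cut-off is unknown, so none is imposed).
Self-loops are dropped; duplicate unordered pairs collapse to the maximum
confidence (conservative retention of the strongest evidence). Components
with fewer than `min_component_size` = 5 nodes are removed and by default
only the largest component is kept, ties broken by the component holding
the lexicographically smallest gene id (determinism for testing). Both
behaviors are exposed separately because "remove small components" and
"keep the largest" differ when several large components exist.

**Layer assignment.** Localization labels map to canonical layers through
an explicit table; anything mapping only to "other" (mitochondrion,
secreted, …) counts as unannotated, since the three-layer model has no
fourth stratum. Multi-localized proteins resolve by a priority order,
default (plasma_membrane, cytoplasm, nucleus) — one node, one layer.
Unannotated nodes take the majority layer among annotated nodes at
minimal breadth-first distance, ties broken by the same priority order;
provenance (annotated vs propagated) is kept per node. Nodes that cannot
reach any annotated node are an error rather than a silent guess.
Percentages in the distribution table are half-up rounded to one decimal
(`Decimal`, not banker's rounding); with half-up rounding the published
nucleus cell of the reference table cannot be reproduced from its own
counts (108/339 = 31.86 vs a printed 31.8), so only the plasma-membrane
and cytoplasm cells are used as checks.

**Over-representation.** For each layer with gene count n inside a
background of N genes, a term with K members in the background and
x ≥ `min_hits` (default 2) hits is scored with the hypergeometric upper
tail P(X ≥ x) (scipy's survival function). The Bonferroni factor m is the
number of terms actually tested in that layer — the "terms tested"
semantics of the correction, as annotation servers apply it. An optional
EASE-style variant (one hit discounted) is available behind the `ease`
flag. The default background is every gene in the expression matrix; a
network-restricted background is selectable. Caveat, verified by
simulation in the test suite: counting only tested terms makes the
correction anticonservative when layers are very small (few genes ⇒ few
terms reach `min_hits` ⇒ small m), inflating the family-wise rate by up
to (catalog size)/(tested terms). Under the fully null benchmark the
realized family-wise rate stays below 5 % (the acceptance script
recomputes it); under nulls with many differential genes and tiny layers
it can exceed the nominal level. Users who need strict control at any
layer size should set m to the catalog size by testing with
`min_hits=1`.

**Annotation grouping.** Significant terms of a layer are compared by
Cohen's kappa over binary memberships of their *hit genes*, with the
layer's differential gene set as the reference universe (the binary
gene–term matrix is built from the analyzed cluster, not the whole
genome). Pairs with κ > `kappa_threshold` (default 0.3, strict) are
linked. Initial groups are closed neighborhoods of every linked term;
singletons stand alone. Any two groups sharing ≥ `share_threshold`
(default 0.5) of the smaller group's terms merge, highest-sharing pair
first, ties broken by the lexicographically smallest combined member
tuple; the group count strictly decreases, so a fixed point is reached.
When both memberships are constant over the reference (p_e = 1), κ is
defined as 1 for identical memberships and 0 otherwise. Each member term
is typed up/down when its hit-gene up-fraction passes
`pct_up_threshold` (default 0.6) from above or below; the group label is
the minimum-adjusted-p up term and/or down term (the overall minimum-p
member if all terms are mixed), and the group direction applies the same
threshold to the union of hit genes.

**Seed subnetworks.** Given seed genes (explicit, or "all layer genes
annotated to term T"), the subnetwork is the induced graph over seeds and
their direct neighbors, each neighbor ranked by the number of distinct
seeds it touches; neighbors adjacent to every seed form the core tier.
Only 1-hop neighborhoods are considered — the display this mirrors shows
direct interactions only.

## The synthetic benchmark

The generator emulates the four inputs with planted truth:

* **Expression**: per-gene baseline ~ N(8, 1) in arbitrary log-like
  units, i.i.d. Gaussian noise with σ = `noise_sd` = 1, and a condition
  shift of ±`effect_size`·σ (default 3) on group A for planted
  differential genes. Defaults: 1,000 genes, 6 samples per group, 10 %
  differential, half up. The 3σ effect at n = 6/group gives per-gene
  t-test power above 0.99 (noncentrality 3·√3), so planted genes are
  recovered at the 95 % level demanded of the end-to-end benchmark.
* **Catalog**: 60 terms; each planted term (default: one 8-gene cytoplasm
  up term) draws `signal_genes` = 7 members from differential genes of
  its layer and direction and the rest from non-differential genes of the
  same layer, so the term's modal true layer is the planted layer; the
  other terms are uniform random sets of 5–25 genes.
* **Network**: Erdős–Rényi background at density 0.01 plus a dense module
  (density 0.9) over each planted term's signal genes; isolated nodes are
  attached to a random module gene so the largest-component filter has
  non-trivial behavior. Pair sampling is O(n²), fine at benchmark scale.
* **Localization**: each gene's true layer is drawn from
  `layer_proportions` (default roughly uniform); 10 % of genes carry no
  record, and annotated genes use raw synonyms of their true layer
  (occasionally plus an "other" compartment), exercising the label map
  and the priority rule without cross-layer conflicts.

All randomness flows from `rng_seed`; identical configs give
byte-identical fixtures.

What the generator does **not** emulate: probe-level structure,
normalization and batch effects; correlated noise between genes;
scale-free network topology and degree-dependent annotation bias;
multi-layer proteins whose records genuinely conflict; hierarchical term
catalogs (GO graph propagation is out of scope — annotations are flat
sets). Passing the planted-recovery tests therefore demonstrates that the
pipeline's machinery is correct and calibrated under clean assumptions,
not that any particular biological dataset will yield stable groups.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use the default benchmark
scale (1,000 genes, 60 terms): 200 seeded end-to-end replicates for
planted recovery in the suite (100 in the script), 100 fully null
replicates for family-wise calibration, exhaustive enumeration of the
hypergeometric tail for all backgrounds N ≤ 12, 1,000 random membership
pairs against an independent kappa implementation, and brute-force
adjacency checks on graphs of ≤ 20 nodes.

## Known limitations

* The DE stage is a plain t-test on the given matrix; no moderation
  (limma-style shrinkage), pairing or log-transformation is applied.
* Tested-only Bonferroni (see above) is anticonservative for very small
  layers.
* Group merging is O(g³) in the number of initial groups per layer —
  irrelevant at realistic term counts, noticeable beyond a few thousand
  significant terms.
* Layer propagation assumes the filtered network is connected (default
  filters guarantee it); with `keep_largest_only=false` an isolated
  unannotated component is an error by design.
* Exported GraphML coordinates are a deterministic tiered/concentric
  layout, not an aesthetic edge-crossing-minimized one.
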