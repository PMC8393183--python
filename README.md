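# mesoconnect

Bottom-up transcriptome-to-connectome network analysis.

Given a nonnegative expression matrix with genes as rows and brain regions
as columns, `mesoconnect` derives, in order:

1. **Variant genes** — per-gene log10 sample variance across regions,
   with a cutoff selected by sweeping thresholds in 0.1 increments and
   locating the point where the retained-gene curve both drops fastest
   (first derivative minimal) and flattens out (second derivative maximal).
2. **A gene co-expression network (GRN)** — each gene's regional profile is
   normalized to a probability distribution; pairs are scored with the
   Jensen–Shannon divergence, JSD(p‖q) = ½KL(p‖m) + ½KL(q‖m) with
   m = (p+q)/2 and base-2 logarithms so JSD ∈ [0, 1].  Edges keep the
   lowest-divergence pairs, with the percentile cutoff chosen where the
   Shannon entropy of the betweenness-centrality distribution is maximal.
   A single-layer metric panel (degree, betweenness, closeness, eigenvector
   centrality, degree assortativity) describes the result.
3. **Gene communities** — Newman's leading-eigenvector method: recursive
   bisection along the sign structure of the dominant eigenvector of the
   modularity matrix B = A − kkᵀ/2m, maximizing
   Q = (1/2m) Σᵢⱼ Bᵢⱼ δ(cᵢ, cⱼ), with single-node fine-tuning of each
   split.  Communities smaller than 10 genes are dissolved; communities
   larger than 150 genes are recursively re-examined.  Repeated seeded runs
   give a stability report, and a one-way ANOVA compares the observed
   modularities against Erdős–Rényi G(n, m) null models.
4. **A community-layered multiplex ("mesoconnectome")** — one layer per
   gene community: regions are compared by the JSD of their expression
   profiles restricted to that community's genes, thresholded at the mode
   of the pooled divergence distribution.  Layers are node-aligned with
   categorical interlayer coupling of weight ω.  Multilayer degree,
   PageRank, eigenvector centrality and k-core are computed on the
   supra-adjacency matrix.
5. **Brain modules** — generalized (multilayer) Louvain on the Mucha-style
   supra-modularity matrix (intra-layer Newman–Girvan terms at resolution
   γ plus replica couplings ω), with per-layer projected modularity and a
   region-by-region summary of connectivity through shared modules.

A seeded synthetic-data generator plants gene communities, region modules
and a low-variance background, so every stage can be validated by parameter
recovery without any external download.

## Worked example

```python
import mesoconnect as mc

cfg = mc.SyntheticConfig(seed=7)          # 600 genes x 60 regions, 4 planted
expr, truth = mc.generate(cfg)            # communities, half background

vt = mc.gene_log_variance(expr)
sweep = mc.sweep_variance_threshold(vt)
variant = mc.variant_gene_ids(vt, sweep.selected_threshold)
print(f"variance threshold: {sweep.selected_threshold:.1f}  "
      f"variant genes: {len(variant)}")

div = mc.pairwise_divergence(expr.subset(variant), axis="genes")
es = mc.betweenness_entropy_sweep(div)
g = mc.build_grn(div, es.selected_divergence_value)
print(f"edge percentile: {es.selected_percentile}  "
      f"GRN: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")

part = mc.refine_communities(
    mc.leading_eigenvector_communities(g, seed=1), g, seed=1)
print(f"communities: {part.sizes}  Q = {part.modularity:.3f}")

est = {v: part.node_to_label[v] for v in g}
tru = {v: truth.gene_to_community[v] for v in g}
nmi, ari = mc.evaluate_recovery(est, tru)
print(f"recovery vs planted truth: NMI = {nmi:.3f}, ARI = {ari:.3f}")
```

prints

```
variance threshold: -1.9  variant genes: 323
edge percentile: 14  GRN: 323 nodes, 7281 edges
communities: {'c1': 75, 'c2': 75, 'c3': 75, 'c4': 75, 'c5': 23}  Q = 0.765
recovery vs planted truth: NMI = 1.000, ARI = 1.000
```

The variance sweep cuts just above the flat background population
(log10 variance ≈ −2), keeping the 300 planted community genes plus a thin
background tail.  The entropy sweep thresholds the JSD matrix at the 14th
percentile; spectral community detection then recovers the four planted
75-gene communities exactly (the fifth, 23-gene community is the residual
background tail, which also matches the ground-truth labeling).

The same run is available from the shell:

```sh
mesoconnect run --config config.yaml       # all stages + manifest.json
mesoconnect simulate --outdir out --seed 7 --n-genes 600 --n-regions 60
mesoconnect grn --outdir out --edge-percentile 25   # stage-wise, overridable
```

Every stage writes TSV/GraphML/JSON outputs and echoes its numeric
decisions (thresholds, percentiles, counts, modularities) into
`manifest.json`, so a run is fully auditable and reruns with the same
config and seeds are bit-identical.

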