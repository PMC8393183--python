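"""End-to-end orchestration: preprocess -> GRN -> communities -> multiplex -> modules.

Every stage reads its inputs from files written by the previous stage, so
each can also run standalone; all numeric decisions (thresholds, percentiles,
counts, modularities) are echoed into a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .communities import (
    UNASSIGNED,
    Partition,
    community_stability,
    er_null_comparison,
    leading_eigenvector_communities,
    refine_communities,
)
from .expression import (
    ExpressionMatrix,
    filter_blacklist,
    gene_log_variance,
    load_blacklist,
    load_expression,
    sweep_variance_threshold,
    variant_gene_ids,
)
from .grn import (
    betweenness_entropy_sweep,
    build_grn,
    grn_metric_panel,
    pairwise_divergence,
)
from .modules import (
    multilayer_louvain,
    region_majority_modules,
    region_module_summary,
)
from .multiplex import (
    build_multiplex,
    kcore_distribution,
    layer_divergence,
    mode_threshold,
    multiplex_degree,
    multiplex_eigenvector,
    multiplex_kcore,
    multiplex_pagerank,
    read_extended_edgelist,
    write_extended_edgelist,
)
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULTS",
           "stage_preprocess", "stage_grn", "stage_communities",
           "stage_multiplex", "stage_modules"]

DEFAULTS = {
    "seed": 0,
    "variance_step": 0.1,
    "edge_percentile": None,  # override; None -> entropy sweep
    "min_community": 10,
    "max_community": 150,
    "runs": 30,
    "null_models": 30,
    "omega": 1.0,
    "gamma": 1.0,
    "damping": 0.85,
}


def _merged(config: dict) -> dict:
    merged = dict(DEFAULTS)
    merged.update(config or {})
    return merged


def _load_input(config: dict, outdir: Path) -> ExpressionMatrix:
    if "simulate" in config:
        sim = SyntheticConfig(**config["simulate"])
        expr, truth = generate(sim)
        expr.to_tsv(outdir / "expression.tsv")
        pd.Series(truth.gene_to_community, name="community").rename_axis(
            "gene_id").to_csv(outdir / "truth_gene_communities.tsv", sep="\t")
        pd.Series(truth.region_to_module, name="module").rename_axis(
            "region").to_csv(outdir / "truth_region_modules.tsv", sep="\t")
        return expr
    if "input" not in config:
        raise ValueError("config needs either an 'input' path or a 'simulate' block")
    return load_expression(config["input"])


def stage_preprocess(config: dict, outdir: Path) -> dict:
    config = _merged(config)
    expr = _load_input(config, outdir)
    n_loaded = expr.n_genes
    if config.get("blacklist"):
        expr = filter_blacklist(expr, load_blacklist(config["blacklist"]))
    vt = gene_log_variance(expr)
    sweep = sweep_variance_threshold(vt, step=config["variance_step"])
    vt.to_frame().to_csv(outdir / "variance_table.tsv", sep="\t")
    sweep.to_frame().to_csv(outdir / "variance_sweep.tsv", sep="\t", index=False)
    variant = variant_gene_ids(vt, sweep.selected_threshold)
    expr.subset(variant).to_tsv(outdir / "variant_expression.tsv")
    return {
        "n_genes_loaded": n_loaded,
        "n_genes_after_blacklist": expr.n_genes,
        "variance_threshold": sweep.selected_threshold,
        "n_variant_genes": len(variant),
        "outputs": {
            "variance_table": "variance_table.tsv",
            "variance_sweep": "variance_sweep.tsv",
            "variant_expression": "variant_expression.tsv",
        },
    }


def stage_grn(config: dict, outdir: Path) -> dict:
    config = _merged(config)
    expr = load_expression(outdir / "variant_expression.tsv")
    div = pairwise_divergence(expr, axis="genes")
    offdiag = div.offdiagonal()
    if config["edge_percentile"] is not None:
        percentile = int(config["edge_percentile"])
        cutoff = float(np.percentile(offdiag, percentile))
        entropy_at_selected = None
    else:
        sweep = betweenness_entropy_sweep(div)
        sweep.to_frame().to_csv(outdir / "entropy_sweep.tsv", sep="\t",
                                index=False)
        percentile = sweep.selected_percentile
        cutoff = sweep.selected_divergence_value
        entropy_at_selected = float(sweep.entropy.max())
    g = build_grn(div, cutoff)
    nx.write_graphml(g, outdir / "grn.graphml")
    nx.to_pandas_edgelist(g).to_csv(outdir / "grn_edges.tsv", sep="\t",
                                    index=False)
    panel = grn_metric_panel(g) if g.number_of_nodes() else None
    if panel is not None:
        panel.per_node.to_csv(outdir / "grn_metrics.tsv", sep="\t")
        panel.neighbor_degree_curve.to_csv(
            outdir / "grn_degree_assortativity_curve.tsv", sep="\t", index=False)
    return {
        "edge_percentile": percentile,
        "edge_divergence_cutoff": cutoff,
        "betweenness_entropy": entropy_at_selected,
        "grn_nodes": g.number_of_nodes(),
        "grn_edges": g.number_of_edges(),
        "assortativity": None if panel is None else panel.assortativity,
        "outputs": {
            "grn_graphml": "grn.graphml",
            "grn_edges": "grn_edges.tsv",
            "grn_metrics": "grn_metrics.tsv",
        },
    }


def stage_communities(config: dict, outdir: Path) -> dict:
    config = _merged(config)
    g = nx.read_graphml(outdir / "grn.graphml")
    seed = int(config["seed"])
    part = leading_eigenvector_communities(g, seed=seed)
    part = refine_communities(part, g, min_size=config["min_community"],
                              max_size=config["max_community"], seed=seed)
    pd.Series(part.node_to_label, name="community").rename_axis("gene_id") \
        .sort_index().to_csv(outdir / "gene_communities.tsv", sep="\t")
    result = {
        "modularity": part.modularity,
        "community_sizes": {k: v for k, v in sorted(part.sizes.items())
                            if k != UNASSIGNED},
        "n_communities": len(part.communities()),
        "n_unassigned": part.sizes.get(UNASSIGNED, 0),
        "outputs": {"gene_communities": "gene_communities.tsv"},
    }
    runs = int(config["runs"])
    if runs >= 2:
        report = community_stability(
            g, runs=runs, base_seed=seed,
            min_size=config["min_community"], max_size=config["max_community"])
        null = er_null_comparison(g, report.modularity_samples,
                                  n_null=int(config["null_models"]), seed=seed)
        stability = {
            "runs": runs,
            "modularity_samples": report.modularity_samples.tolist(),
            "label_agreement": report.label_agreement,
            "null_modularities": null.null_modularities.tolist(),
            "f_statistic": null.f_statistic,
            "p_value": null.p_value,
        }
        with open(outdir / "stability.json", "wt") as fh:
            json.dump(stability, fh, indent=2)
        result["mean_modularity"] = float(report.modularity_samples.mean())
        result["label_agreement"] = report.label_agreement
        result["null_mean_modularity"] = float(null.null_modularities.mean())
        result["anova_f"] = null.f_statistic
        result["anova_p"] = null.p_value
        result["outputs"]["stability"] = "stability.json"
    return result


def stage_multiplex(config: dict, outdir: Path) -> dict:
    config = _merged(config)
    expr = load_expression(outdir / "variant_expression.tsv")
    labels = pd.read_csv(outdir / "gene_communities.tsv", sep="\t",
                         index_col=0)["community"]
    communities = {
        lab: sorted(idx)
        for lab, idx in labels.groupby(labels).groups.items()
        if lab != UNASSIGNED
    }
    layers, layer_labels = [], []
    for lab in sorted(communities):
        genes = [g for g in communities[lab] if g in set(expr.gene_ids)]
        if len(genes) < 2:
            continue
        layers.append(layer_divergence(expr, genes, community_label=lab))
        layer_labels.append(lab)
    if not layers:
        raise ValueError("no usable community layers")
    pooled = np.concatenate([d.offdiagonal() for d in layers])
    mode, mode_percentile = mode_threshold(pooled)
    net = build_multiplex(layers, mode, layer_labels=layer_labels,
                          coupling_weight=float(config["omega"]))
    write_extended_edgelist(net, outdir / "multiplex_edges.tsv")
    degree = multiplex_degree(net)
    pagerank, _ = multiplex_pagerank(net, damping=float(config["damping"]))
    eigen, _ = multiplex_eigenvector(net)
    coreness = multiplex_kcore(net)
    metrics = pd.concat([degree, pagerank, eigen, coreness], axis=1)
    metrics.rename_axis("region").to_csv(outdir / "multiplex_metrics.tsv",
                                         sep="\t")
    return {
        "n_layers": net.n_layers,
        "multiplex_cutoff": mode,
        "multiplex_cutoff_percentile": mode_percentile,
        "intra_layer_edges": {
            lab: int(a.sum() // 2)
            for lab, a in zip(net.layer_labels, net.adjacency)
        },
        "max_coreness": int(coreness.max()),
        "kcore_distribution": {str(k): v for k, v in
                               kcore_distribution(coreness).items()},
        "outputs": {
            "multiplex_edges": "multiplex_edges.tsv",
            "multiplex_metrics": "multiplex_metrics.tsv",
        },
    }


def stage_modules(config: dict, outdir: Path) -> dict:
    config = _merged(config)
    net = read_extended_edgelist(outdir / "multiplex_edges.tsv")
    expr = load_expression(outdir / "variant_expression.tsv")
    labels = pd.read_csv(outdir / "gene_communities.tsv", sep="\t",
                         index_col=0)["community"]
    part = Partition({g: lab for g, lab in labels.items()}, float("nan"))
    assign = multilayer_louvain(net, gamma=float(config["gamma"]),
                                omega=float(config["omega"]),
                                seed=int(config["seed"]))
    rows = [(r, lay, mod) for (r, lay), mod in
            sorted(assign.node_layer_to_module.items())]
    pd.DataFrame(rows, columns=["region", "layer", "module"]).to_csv(
        outdir / "brain_modules.tsv", sep="\t", index=False)
    pd.Series(assign.per_layer_modularity, name="modularity").rename_axis(
        "layer").to_csv(outdir / "layer_modularity.tsv", sep="\t")
    summary = region_module_summary(assign, part, expr, net)
    summary.shared_layers.rename_axis("region").to_csv(
        outdir / "region_shared_layers.tsv", sep="\t")
    summary.shared_genes.rename_axis("region").to_csv(
        outdir / "region_shared_genes.tsv", sep="\t")
    summary.connectivity_rank.rename_axis("region").to_csv(
        outdir / "region_connectivity_rank.tsv", sep="\t")
    region_majority_modules(assign, net).rename_axis("region").to_csv(
        outdir / "region_modules.tsv", sep="\t")
    return {
        "n_modules": assign.n_modules,
        "supra_modularity": assign.supra_modularity,
        "per_layer_modularity": dict(sorted(
            assign.per_layer_modularity.items())),
        "outputs": {
            "brain_modules": "brain_modules.tsv",
            "layer_modularity": "layer_modularity.tsv",
            "region_modules": "region_modules.tsv",
            "region_shared_layers": "region_shared_layers.tsv",
            "region_shared_genes": "region_shared_genes.tsv",
            "region_connectivity_rank": "region_connectivity_rank.tsv",
        },
    }


_STAGES = [
    ("preprocess", stage_preprocess),
    ("grn", stage_grn),
    ("communities", stage_communities),
    ("multiplex", stage_multiplex),
    ("modules", stage_modules),
]


def run_pipeline(config: dict) -> dict:
    """Run all stages in order, writing outputs and a JSON run manifest.

    A failure mid-run leaves the completed stages' outputs in place and a
    partial manifest marked ``"status": "failed"``.
    """
    if "outdir" not in config:
        raise ValueError("config must name an output directory ('outdir')")
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mesoconnect",
        "version": __version__,
        "config": {k: v for k, v in _merged(config).items() if k != "outdir"},
        "status": "running",
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"
    for name, fn in _STAGES:
        logger.info("=== stage %s ===", name)
        try:
            manifest["stages"][name] = fn(config, outdir)
        except Exception as exc:
            manifest["status"] = "failed"
            manifest["failed_stage"] = name
            manifest["error"] = f"{type(exc).__name__}: {exc}"
            with open(manifest_path, "wt") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        with open(manifest_path, "wt") as fh:
            json.dump(manifest, fh, indent=2)
    manifest["status"] = "ok"
    with open(manifest_path, "wt") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
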