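"""Jensen-Shannon divergence graphs and the single-layer metric panel.

Each gene's expression profile across brain regions is normalized to a
probability distribution; pairwise Jensen-Shannon divergence (base-2 logs, so
the value lives in [0, 1]) measures how differently two genes are deployed
across the brain.  Gene pairs with low divergence are linked, the cutoff being
chosen where the Shannon entropy of the resulting betweenness-centrality
distribution is maximal — the graph that spreads shortest-path traffic most
evenly over its nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import entr, rel_entr

from .expression import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)

__all__ = [
    "DivergenceMatrix",
    "EntropySweep",
    "MetricPanel",
    "normalize_profile",
    "jensen_shannon_divergence",
    "pairwise_divergence",
    "betweenness_entropy",
    "betweenness_entropy_sweep",
    "build_grn",
    "grn_metric_panel",
]


@dataclass
class DivergenceMatrix:
    """Symmetric pairwise JSD in [0, 1] with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("divergence matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValidationError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("divergence matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("divergence diagonal must be zero")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("divergences must lie in [0, 1]")
        self.values = np.clip((v + v.T) / 2, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal values, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class EntropySweep:
    """Betweenness-distribution entropy for each candidate percentile cutoff."""

    percentile_grid: np.ndarray
    entropy: np.ndarray
    selected_percentile: int
    selected_divergence_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"percentile": self.percentile_grid, "entropy": self.entropy}
        )


@dataclass
class MetricPanel:
    """Single-layer GRN metrics: per-node table plus graph-level scalars."""

    per_node: pd.DataFrame  # degree, betweenness, closeness, eigenvector
    assortativity: float  # Pearson degree assortativity; NaN when degenerate
    neighbor_degree_curve: pd.DataFrame  # mean neighbor degree vs. degree


def normalize_profile(row: np.ndarray, label: str | None = None) -> np.ndarray:
    """Scale a nonnegative vector to a probability distribution."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValidationError(f"negative entry in profile {label or ''}".strip())
    total = row.sum()
    if total <= 0:
        raise ValidationError(
            f"profile {label!r} is all zero and cannot be normalized"
            if label is not None
            else "all-zero profile cannot be normalized"
        )
    return row / total


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p||q) = 0.5 KL(p||m) + 0.5 KL(q||m), m the equal mixture, in bits.

    With base-2 logarithms the value is 0 for identical distributions and 1
    for distributions with disjoint support.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("distributions differ in length")
    if (p < 0).any() or (q < 0).any():
        raise ValidationError("negative probability entry")
    if abs(p.sum() - 1) > 1e-9 or abs(q.sum() - 1) > 1e-9:
        raise ValidationError("inputs must sum to 1 (within 1e-9)")
    m = (p + q) / 2
    d = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / _LN2
    return float(min(max(d, 0.0), 1.0))


def _rows_to_distributions(rows: np.ndarray, labels: list[str]) -> np.ndarray:
    sums = rows.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"profile {labels[bad[0]]!r} is all zero and cannot be normalized"
        )
    return rows / sums[:, None]


def _pairwise_jsd(P: np.ndarray) -> np.ndarray:
    """All-pairs JSD of row distributions via JSD = H(m) - (H(p)+H(q))/2."""
    n = P.shape[0]
    H = entr(P).sum(axis=1) / _LN2
    D = np.zeros((n, n))
    for i in range(n - 1):
        mix = (P[i] + P[i + 1:]) / 2
        Hm = entr(mix).sum(axis=1) / _LN2
        d = Hm - (H[i] + H[i + 1:]) / 2
        D[i, i + 1:] = D[i + 1:, i] = np.clip(d, 0.0, 1.0)
    return D


def pairwise_divergence(expr: ExpressionMatrix, axis: str = "genes") -> DivergenceMatrix:
    """Pairwise JSD between gene rows (axis='genes') or region columns."""
    if axis == "genes":
        rows, labels = expr.values, list(expr.gene_ids)
    elif axis == "regions":
        rows, labels = expr.values.T, list(expr.region_labels)
    else:
        raise ValueError(f"axis must be 'genes' or 'regions', got {axis!r}")
    P = _rows_to_distributions(np.asarray(rows, dtype=float), labels)
    return DivergenceMatrix(labels, _pairwise_jsd(P))


def betweenness_entropy(graph: ig.Graph) -> float:
    """Shannon entropy (natural log) of the betweenness distribution.

    The node betweenness values are binned into an equal-width histogram with
    ceil(sqrt(n)) bins over [0, max]; the entropy of the bin-occupancy
    distribution is returned.  A graph whose betweenness is constant (e.g. a
    complete graph, where it is all zero) has entropy 0: the distribution is
    degenerate.  This is what makes the percentile sweep peak at intermediate
    densities — very sparse graphs concentrate traffic on a few bridges and
    very dense graphs flatten it to a single value, while mid-density graphs
    spread betweenness over many distinct magnitudes.
    """
    b = np.asarray(graph.betweenness(), dtype=float)
    if b.size == 0 or np.ptp(b) == 0:
        return 0.0
    n_bins = int(np.ceil(np.sqrt(b.size)))
    counts, _ = np.histogram(b, bins=n_bins, range=(0.0, b.max()))
    p = counts[counts > 0] / b.size
    return float(entr(p).sum())


def betweenness_entropy_sweep(
    d: DivergenceMatrix, grid: np.ndarray | None = None
) -> EntropySweep:
    """Scan percentile cutoffs and score each thresholded graph's entropy.

    For percentile p the graph keeps edges with divergence <= the p-th
    percentile of the upper-triangle off-diagonal divergences.  The selected
    percentile attains the maximum entropy (ties -> smallest percentile).
    """
    if d.n < 3:
        raise ValidationError("entropy sweep needs at least 3 nodes")
    grid = np.arange(1, 100) if grid is None else np.asarray(grid, dtype=int)
    if grid.size == 0:
        raise ValidationError("empty percentile grid")
    offdiag = d.offdiagonal()
    iu = np.triu_indices(d.n, k=1)
    entropies = np.empty(grid.size)
    for gi, p in enumerate(grid):
        cutoff = np.percentile(offdiag, p)
        keep = offdiag <= cutoff
        edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
        g = ig.Graph(n=d.n, edges=edges)
        entropies[gi] = betweenness_entropy(g)
    best = int(np.argmax(entropies))
    selected_p = int(grid[best])
    value = float(np.percentile(offdiag, selected_p))
    logger.info(
        "entropy sweep selected percentile %d (divergence cutoff %.6f)",
        selected_p, value,
    )
    return EntropySweep(grid, entropies, selected_p, value)


def build_grn(d: DivergenceMatrix, cutoff_value: float) -> nx.Graph:
    """Binarize the divergence matrix: edge iff divergence <= cutoff.

    Nodes left without any edge are removed, so the returned graph has
    minimum degree 1 (it may be empty).
    """
    if not 0 <= cutoff_value <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(d.labels)
    iu, ju = np.triu_indices(d.n, k=1)
    keep = d.values[iu, ju] <= cutoff_value
    g.add_edges_from(
        (d.labels[i], d.labels[j]) for i, j in zip(iu[keep], ju[keep])
    )
    isolated = [v for v, deg in g.degree() if deg == 0]
    g.remove_nodes_from(isolated)
    logger.info(
        "GRN: %d nodes, %d edges (%d isolated nodes dropped)",
        g.number_of_nodes(), g.number_of_edges(), len(isolated),
    )
    return g


def grn_metric_panel(g: nx.Graph) -> MetricPanel:
    """Degree, betweenness, closeness and eigenvector centrality per node,
    plus degree assortativity and the mean-neighbor-degree curve.

    Betweenness is unnormalized.  On disconnected graphs eigenvector
    centrality is computed on the largest component (others get 0) with a
    warning.  Assortativity is NaN when every node has the same degree.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("metric panel needs a nonempty graph")
    nodes = list(g)
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.closeness_centrality(g)

    if nx.is_connected(g):
        eig_graph = g
    else:
        warnings.warn(
            "graph is disconnected; eigenvector centrality reported for the "
            "largest component only", stacklevel=2,
        )
        eig_graph = g.subgraph(max(nx.connected_components(g), key=len))
    eig = {v: 0.0 for v in nodes}
    if eig_graph.number_of_edges() > 0:
        eig.update(nx.eigenvector_centrality(eig_graph, max_iter=2000, tol=1e-10))

    degs = np.array([degree[v] for v in nodes], dtype=float)
    if np.ptp(degs) == 0:
        warnings.warn(
            "all nodes share the same degree; assortativity undefined",
            stacklevel=2,
        )
        assort = float("nan")
    else:
        assort = float(nx.degree_assortativity_coefficient(g))

    avg_nbr = nx.average_neighbor_degree(g)
    per_node = pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
            "mean_neighbor_degree": [avg_nbr[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    curve = (
        per_node.groupby("degree")["mean_neighbor_degree"]
        .mean()
        .reset_index()
        .rename(columns={"mean_neighbor_degree": "mean_neighbor_degree"})
    )
    return MetricPanel(per_node=per_node, assortativity=assort,
                       neighbor_degree_curve=curve)
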