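"""Community-layered multiplex over brain regions and its multilayer metrics.

Each gene community induces one layer: regions are compared by the JSD of
their expression profiles restricted to that community's genes, and region
pairs below a cutoff are linked.  The cutoff is the mode of the pooled
divergence distribution (Freedman-Diaconis histogram), keeping the least
divergent region pairs in every layer.  The layers are node-aligned, with
categorical interlayer coupling (every replica pair of a region, weight
omega).  Multilayer degree, PageRank, eigenvector centrality and k-core are
computed on the supra-adjacency matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .expression import ExpressionMatrix, ValidationError
from .grn import DivergenceMatrix, _pairwise_jsd

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexNetwork",
    "layer_divergence",
    "mode_threshold",
    "build_multiplex",
    "multiplex_degree",
    "multiplex_pagerank",
    "multiplex_eigenvector",
    "multiplex_kcore",
    "kcore_distribution",
    "write_extended_edgelist",
    "read_extended_edgelist",
]


@dataclass
class MultiplexNetwork:
    """Node-aligned layered network over brain regions.

    ``adjacency`` holds one symmetric 0/1 matrix per layer (no self-loops).
    Interlayer coupling is categorical: every region is linked to each of its
    replicas in the other layers with weight ``omega``.
    """

    region_labels: list[str]
    layer_labels: list[str]
    adjacency: list[np.ndarray]
    omega: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.region_labels)
        if len(self.adjacency) != len(self.layer_labels):
            raise ValidationError("one adjacency matrix per layer required")
        mats = []
        for lab, a in zip(self.layer_labels, self.adjacency):
            a = np.asarray(a, dtype=float)
            if a.shape != (n, n):
                raise ValidationError(f"layer {lab!r} adjacency has wrong shape")
            if not np.allclose(a, a.T):
                raise ValidationError(f"layer {lab!r} adjacency not symmetric")
            if np.abs(np.diag(a)).max(initial=0.0) > 0:
                raise ValidationError(f"layer {lab!r} has self-loops")
            mats.append((a > 0).astype(float))
        self.adjacency = mats
        if self.omega < 0:
            raise ValidationError("coupling weight omega must be >= 0")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_layers(self) -> int:
        return len(self.layer_labels)

    def intra_edges(self, layer: int) -> list[tuple[str, str]]:
        iu, ju = np.nonzero(np.triu(self.adjacency[layer], k=1))
        return [(self.region_labels[i], self.region_labels[j])
                for i, j in zip(iu, ju)]

    def supra_adjacency(self) -> sparse.csr_matrix:
        """(N*L) x (N*L) matrix: intra-layer blocks on the diagonal, omega
        couplings between all replica pairs.  Node-layer order: layer-major."""
        n, L = self.n_regions, self.n_layers
        blocks = sparse.block_diag(
            [sparse.csr_matrix(a) for a in self.adjacency], format="lil"
        )
        if self.omega > 0 and L > 1:
            eye = sparse.eye(n, format="lil") * self.omega
            for s in range(L):
                for r in range(L):
                    if s != r:
                        blocks[s * n:(s + 1) * n, r * n:(r + 1) * n] = eye
        return sparse.csr_matrix(blocks)


def layer_divergence(
    expr: ExpressionMatrix,
    community_genes,
    community_label: str | None = None,
) -> DivergenceMatrix:
    """Region x region JSD restricted to one community's genes."""
    community_genes = sorted(set(community_genes))
    if len(community_genes) < 2:
        raise ValidationError("a layer needs at least 2 community genes")
    missing = set(community_genes) - set(expr.gene_ids)
    if missing:
        raise ValidationError(
            f"community genes not in expression matrix: {sorted(missing)[:3]}"
        )
    sub = expr.subset(community_genes)
    profiles = sub.values.T  # regions x community genes
    sums = profiles.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"region {expr.region_labels[bad[0]]!r} has all-zero expression "
            f"for community {community_label!r}"
        )
    P = profiles / sums[:, None]
    return DivergenceMatrix(list(expr.region_labels), _pairwise_jsd(P))


def mode_threshold(pooled_values) -> tuple[float, float]:
    """Mode of the pooled divergence distribution and its percentile rank.

    A Freedman-Diaconis histogram is built over the pooled off-diagonal
    divergences of all layers; the mode is the midpoint of the most populated
    bin (ties -> lowest bin).  The percentile is the fraction of pooled values
    <= mode, times 100 (so a sample of identical values has percentile 100).
    """
    vals = np.asarray(pooled_values, dtype=float).ravel()
    if vals.size < 10:
        raise ValidationError("need at least 10 pooled divergences for the mode")
    if np.ptp(vals) == 0:
        return float(vals[0]), 100.0
    counts, edges = np.histogram(vals, bins="fd")
    best = int(np.argmax(counts))  # first maximum -> lowest bin
    mode = float((edges[best] + edges[best + 1]) / 2)
    percentile = float(100.0 * np.mean(vals <= mode))
    logger.info("divergence mode %.6f at percentile %.1f", mode, percentile)
    return mode, percentile


def build_multiplex(
    layers: list[DivergenceMatrix],
    cutoff: float,
    layer_labels: list[str] | None = None,
    coupling_weight: float = 1.0,
) -> MultiplexNetwork:
    """Binarize each layer's divergence matrix: edge iff divergence <= cutoff."""
    if not layers:
        raise ValidationError("no layers supplied")
    region_labels = list(layers[0].labels)
    for d in layers[1:]:
        if list(d.labels) != region_labels:
            raise ValidationError("layers disagree on region labels")
    if layer_labels is None:
        layer_labels = [f"L{i + 1}" for i in range(len(layers))]
    mats = []
    for d in layers:
        a = (d.values <= cutoff).astype(float)
        np.fill_diagonal(a, 0.0)
        mats.append(a)
    net = MultiplexNetwork(region_labels, list(layer_labels), mats,
                           omega=coupling_weight)
    logger.info(
        "multiplex: %d regions x %d layers, %s intra-layer edges",
        net.n_regions, net.n_layers,
        [int(a.sum() // 2) for a in net.adjacency],
    )
    return net


def multiplex_degree(net: MultiplexNetwork) -> pd.Series:
    """Total intra-layer degree per region (interlayer couplings excluded)."""
    total = np.zeros(net.n_regions)
    for a in net.adjacency:
        total += a.sum(axis=1)
    return pd.Series(total.astype(int), index=net.region_labels, name="degree")


def multiplex_pagerank(
    net: MultiplexNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[pd.Series, np.ndarray]:
    """Stationary distribution of the damped supra random walk.

    The supra-adjacency (intra edges plus couplings) is column-normalized;
    dangling node-layers teleport uniformly.  Returns per-region scores
    (summed over layers; they sum to 1) and the full node-layer vector.
    """
    n, L = net.n_regions, net.n_layers
    NL = n * L
    if NL == 0:
        raise ValidationError("empty multiplex")
    A = net.supra_adjacency()
    col_sums = np.asarray(A.sum(axis=0)).ravel()
    dangling = col_sums == 0
    inv = np.zeros(NL)
    inv[~dangling] = 1.0 / col_sums[~dangling]
    T = A @ sparse.diags(inv)  # column-stochastic on non-dangling columns

    x = np.full(NL, 1.0 / NL)
    teleport = (1.0 - damping) / NL
    for _ in range(max_iter):
        x_new = damping * (T @ x + x[dangling].sum() / NL) + teleport
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(
            f"PageRank did not converge; residual {np.abs(T @ x - x).sum():.3g}"
        )
    per_region = x.reshape(L, n).sum(axis=0)
    return (
        pd.Series(per_region, index=net.region_labels, name="pagerank"),
        x,
    )


def multiplex_eigenvector(
    net: MultiplexNetwork,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[pd.Series, np.ndarray]:
    """Leading eigenvector of the supra-adjacency by power iteration.

    Per-region scores are summed over layers and rescaled to unit maximum.
    When omega = 0 and the supra graph is disconnected the iteration settles
    on the dominant component; a warning is emitted.
    """
    n, L = net.n_regions, net.n_layers
    A = net.supra_adjacency()
    if A.nnz == 0:
        raise ValidationError("supra-adjacency has no nonzero entries")
    if net.omega == 0 and L > 1:
        n_comp = sparse.csgraph.connected_components(A, directed=False)[0]
        if n_comp > 1:
            warnings.warn(
                "uncoupled multiplex is disconnected; eigenvector centrality "
                "reflects the dominant component", stacklevel=2,
            )
    # positive diagonal shift: same eigenvectors, but keeps bipartite
    # structures (paired +/- eigenvalues) from making the iteration oscillate
    shift = 1.0
    v = np.full(n * L, 1.0)
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = A @ v + shift * v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("supra-adjacency annihilated the start vector")
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError("eigenvector centrality power iteration did not converge")
    v = np.abs(v)
    per_region = v.reshape(L, n).sum(axis=0)
    per_region = per_region / per_region.max()
    return (
        pd.Series(per_region, index=net.region_labels, name="eigenvector"),
        v,
    )


def multiplex_kcore(net: MultiplexNetwork) -> pd.Series:
    """Coreness per region on the total intra-layer degree.

    Iterative pruning: at level k, regions whose total intra-layer degree
    falls below k are removed from all layers simultaneously; a region's
    coreness is the largest k it survives.
    """
    n = net.n_regions
    adj = [a.copy() for a in net.adjacency]
    alive = np.ones(n, dtype=bool)
    coreness = np.zeros(n, dtype=int)

    def degrees() -> np.ndarray:
        d = np.zeros(n)
        for a in adj:
            d += a.sum(axis=1)
        return d

    k = 0
    while alive.any():
        deg = degrees()
        min_deg = int(deg[alive].min())
        k = max(k, min_deg)
        to_remove = alive & (deg <= k)
        while True:
            victims = np.nonzero(to_remove)[0]
            if victims.size == 0:
                break
            coreness[victims] = k
            for a in adj:
                a[victims, :] = 0.0
                a[:, victims] = 0.0
            alive[victims] = False
            if not alive.any():
                break
            deg = degrees()
            to_remove = alive & (deg < k)
    return pd.Series(coreness, index=net.region_labels, name="coreness")


def kcore_distribution(coreness: pd.Series) -> dict[int, float]:
    """P_k(q): fraction of regions with coreness exactly k among regions of
    coreness >= 1."""
    positive = coreness[coreness >= 1]
    if len(positive) == 0:
        return {}
    counts = positive.value_counts().sort_index()
    return {int(k): float(c / len(positive)) for k, c in counts.items()}


def write_extended_edgelist(net: MultiplexNetwork, path) -> None:
    """TSV: node_a, layer_a, node_b, layer_b, weight; couplings included."""
    rows = []
    for li, lab in enumerate(net.layer_labels):
        for a, b in net.intra_edges(li):
            rows.append((a, lab, b, lab, 1.0))
    if net.omega > 0:
        for region in net.region_labels:
            for si in range(net.n_layers):
                for ri in range(si + 1, net.n_layers):
                    rows.append((region, net.layer_labels[si],
                                 region, net.layer_labels[ri], net.omega))
    frame = pd.DataFrame(
        rows, columns=["node_a", "layer_a", "node_b", "layer_b", "weight"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_extended_edgelist(path) -> MultiplexNetwork:
    """Inverse of :func:`write_extended_edgelist`."""
    frame = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str,
                                               "layer_a": str, "layer_b": str})
    intra = frame[frame.layer_a == frame.layer_b]
    coupling = frame[frame.layer_a != frame.layer_b]
    regions = sorted(set(frame.node_a) | set(frame.node_b))
    layers = sorted(set(frame.layer_a) | set(frame.layer_b))
    ridx = {r: i for i, r in enumerate(regions)}
    lidx = {l: i for i, l in enumerate(layers)}
    mats = [np.zeros((len(regions), len(regions))) for _ in layers]
    for row in intra.itertuples(index=False):
        i, j = ridx[row.node_a], ridx[row.node_b]
        mats[lidx[row.layer_a]][i, j] = mats[lidx[row.layer_a]][j, i] = 1.0
    omega = float(coupling.weight.iloc[0]) if len(coupling) else 0.0
    return MultiplexNetwork(regions, layers, mats, omega=omega)
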