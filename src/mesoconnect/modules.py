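"""Brain-module detection on the multiplex by generalized Louvain.

The quality function is the multilayer modularity of Mucha et al.: every
layer contributes a Newman-Girvan term at resolution gamma, and each pair of
replicas of the same region contributes a coupling term omega,

    Q = (1/2mu) sum [ (A_ijs - gamma k_is k_js / 2m_s) delta_sr
                      + delta_ij omega (1 - delta_sr) ] delta(g_is, g_jr)

with 2mu the total edge weight (intra plus coupling).  Optimization is the
Louvain scheme on the supra-modularity matrix: seed-shuffled local moving
followed by community aggregation, repeated until no gain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .communities import Partition
from .expression import ExpressionMatrix, ValidationError
from .multiplex import MultiplexNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "RegionModuleSummary",
    "supra_modularity_matrix",
    "supra_modularity",
    "multilayer_louvain",
    "project_layer_modularity",
    "region_majority_modules",
    "region_module_summary",
]


@dataclass
class ModuleAssignment:
    """(region, layer) -> module label, with supra and per-layer modularity."""

    node_layer_to_module: dict
    n_modules: int
    supra_modularity: float
    per_layer_modularity: dict


@dataclass
class RegionModuleSummary:
    """Region-pair co-assignment counts and shared-gene totals."""

    shared_layers: pd.DataFrame  # region x region, co-assignment counts
    shared_genes: pd.DataFrame  # region x region, underlying gene totals
    connectivity_rank: pd.Series  # 1 = most connected region


def supra_modularity_matrix(
    net: MultiplexNetwork, gamma: float = 1.0, omega: float | None = None
) -> tuple[np.ndarray, float]:
    """Dense supra-modularity matrix B and the normalization 2mu.

    Node-layer order is layer-major (all regions of layer 1, then layer 2...).
    Layers without edges contribute a zero block.
    """
    n, L = net.n_regions, net.n_layers
    omega = net.omega if omega is None else omega
    B = np.zeros((n * L, n * L))
    two_mu = 0.0
    for s, A in enumerate(net.adjacency):
        k = A.sum(axis=1)
        two_m = k.sum()
        sl = slice(s * n, (s + 1) * n)
        if two_m > 0:
            B[sl, sl] = A - gamma * np.outer(k, k) / two_m
            two_mu += two_m
    if omega > 0 and L > 1:
        idx = np.arange(n)
        for s in range(L):
            for r in range(L):
                if s != r:
                    B[s * n + idx, r * n + idx] += omega
        two_mu += n * L * (L - 1) * omega
    if two_mu <= 0:
        raise ValidationError("multiplex has neither edges nor couplings")
    return B, two_mu


def supra_modularity(B: np.ndarray, two_mu: float, labels: np.ndarray) -> float:
    """Direct evaluation of the quality function for a node-layer labeling."""
    q = 0.0
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        q += B[np.ix_(idx, idx)].sum()
    return float(q / two_mu)


def _local_moving(B: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator) -> bool:
    """One round of Louvain local moving on a (signed) weight matrix."""
    n = len(labels)
    improved = False
    moved = True
    while moved:
        moved = False
        order = rng.permutation(n)
        for i in order:
            row = B[i].copy()
            self_w = row[i]
            row[i] = 0.0
            n_labels = labels.max() + 1
            gains = np.bincount(labels, weights=row, minlength=n_labels)
            current = labels[i]
            best = int(np.argmax(gains))
            if gains[best] > gains[current] + 1e-12:
                labels[i] = best
                moved = True
                improved = True
    return improved


def _compress(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _louvain_on_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Full Louvain (local moving + aggregation) maximizing the sum of
    within-community B entries.  Works for signed matrices."""
    node_to_comm = np.arange(B.shape[0])
    Bc = B.copy()
    while True:
        labels = np.arange(Bc.shape[0])
        improved = _local_moving(Bc, labels, rng)
        labels = _compress(labels)
        node_to_comm = labels[node_to_comm]
        n_comm = labels.max() + 1
        if not improved or n_comm == Bc.shape[0]:
            break
        # aggregate: one meta-node per community, summed weights
        onehot = np.zeros((Bc.shape[0], n_comm))
        onehot[np.arange(Bc.shape[0]), labels] = 1.0
        Bc = onehot.T @ Bc @ onehot
    return _compress(node_to_comm)


def multilayer_louvain(
    net: MultiplexNetwork,
    gamma: float = 1.0,
    omega: float | None = None,
    seed: int = 0,
    partition: Partition | None = None,
) -> ModuleAssignment:
    """Detect brain modules by generalized Louvain on the supra matrix.

    ``omega`` defaults to the network's coupling weight.  Module labels are
    integers starting at 1, ordered by module size (desc).  ``partition`` is
    unused here but accepted for interface symmetry with the summary step.
    """
    if net.n_regions == 0 or net.n_layers == 0:
        raise ValidationError("empty multiplex")
    B, two_mu = supra_modularity_matrix(net, gamma=gamma, omega=omega)
    rng = np.random.default_rng(seed)
    labels = _louvain_on_matrix(B, rng)
    q = supra_modularity(B, two_mu, labels)

    # stable module ids: 1..K by decreasing size, ties by first occurrence
    sizes = np.bincount(labels)
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    n, L = net.n_regions, net.n_layers
    assignment = {}
    for s in range(L):
        for i in range(n):
            assignment[(net.region_labels[i], net.layer_labels[s])] = \
                remap[labels[s * n + i]]
    result = ModuleAssignment(
        node_layer_to_module=assignment,
        n_modules=int(sizes[sizes > 0].size),
        supra_modularity=q,
        per_layer_modularity={},
    )
    result.per_layer_modularity = project_layer_modularity(result, net)
    logger.info(
        "multilayer Louvain: %d modules, supra-Q = %.4f",
        result.n_modules, q,
    )
    return result


def project_layer_modularity(
    assign: ModuleAssignment, net: MultiplexNetwork
) -> dict:
    """Newman-Girvan modularity of each layer under the module labels its
    replicas carry.  Edgeless layers get 0 with a warning."""
    out = {}
    for s, lab in enumerate(net.layer_labels):
        A = net.adjacency[s]
        if A.sum() == 0:
            warnings.warn(f"layer {lab!r} has no edges; modularity set to 0",
                          stacklevel=2)
            out[lab] = 0.0
            continue
        g = nx.from_numpy_array(A)
        g = nx.relabel_nodes(g, dict(enumerate(net.region_labels)))
        groups: dict = {}
        for region in net.region_labels:
            groups.setdefault(assign.node_layer_to_module[(region, lab)],
                              set()).add(region)
        out[lab] = float(nx.community.modularity(g, groups.values()))
    return out


def region_majority_modules(assign: ModuleAssignment,
                            net: MultiplexNetwork) -> pd.Series:
    """One module label per region: majority over its layer replicas,
    ties -> lowest module label."""
    out = {}
    for region in net.region_labels:
        labs = [assign.node_layer_to_module[(region, lay)]
                for lay in net.layer_labels]
        counts: dict = {}
        for lab in labs:
            counts[lab] = counts.get(lab, 0) + 1
        best = min(counts, key=lambda lab: (-counts[lab], lab))
        out[region] = best
    return pd.Series(out, name="module")


def region_module_summary(
    assign: ModuleAssignment,
    partition: Partition,
    expr: ExpressionMatrix,
    net: MultiplexNetwork,
) -> RegionModuleSummary:
    """Region-pair connectivity through shared modules.

    ``shared_layers[a, b]`` counts the layers in which regions a and b carry
    the same module label; ``shared_genes[a, b]`` totals the community genes
    underlying those layers.  Regions are ranked by their total shared-layer
    count (rank 1 = most connected).
    """
    regions = net.region_labels
    n = len(regions)
    comm_sizes = {}
    for lab, members in partition.communities().items():
        comm_sizes[lab] = len(members)
    shared = np.zeros((n, n), dtype=int)
    genes = np.zeros((n, n), dtype=int)
    for lay in net.layer_labels:
        lay_genes = comm_sizes.get(lay, 0)
        labs = np.array([assign.node_layer_to_module[(r, lay)] for r in regions])
        same = labs[:, None] == labs[None, :]
        np.fill_diagonal(same, False)
        shared += same
        genes += same * lay_genes
    shared_df = pd.DataFrame(shared, index=regions, columns=regions)
    genes_df = pd.DataFrame(genes, index=regions, columns=regions)
    totals = shared_df.sum(axis=1)
    rank = totals.rank(ascending=False, method="min").astype(int)
    return RegionModuleSummary(shared_df, genes_df,
                               rank.rename("connectivity_rank"))
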