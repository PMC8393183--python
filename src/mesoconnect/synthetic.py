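"""Synthetic expression matrices with planted structure, plus recovery scores.

The generator emulates the statistical shape the pipeline assumes of a brain
transcriptome: a background population of genes that are roughly flat across
regions (low variance), and community genes that share a region-expression
profile up to multiplicative log-normal noise.  Region modules are planted as
block structure in the community profiles: regions of the same module draw
the same gamma-distributed expression level (with a small within-module
jitter), so every community layer sees the same regional block pattern
through a different gene subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .expression import ExpressionMatrix, ValidationError
from .multiplex import MultiplexNetwork

logger = logging.getLogger(__name__)

BACKGROUND = "background"

__all__ = [
    "BACKGROUND",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "generate_planted_multiplex",
    "evaluate_recovery",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-structure generator.

    Defaults follow the fixture the pipeline is validated on: 600 genes over
    60 regions, half background, four gene communities seen through three
    region modules, multiplicative noise sigma 0.1.
    """

    n_genes: int = 600
    n_regions: int = 60
    n_communities: int = 4
    n_region_modules: int = 3
    background_fraction: float = 0.5
    profile_scale: float = 1.0
    noise_sd: float = 0.1
    background_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_fraction < 1:
            raise ValidationError("background_fraction must lie in [0, 1)")
        if self.n_communities < 1 or self.n_region_modules < 1:
            raise ValidationError("need at least one community and one module")
        if self.profile_scale <= 0 or self.noise_sd <= 0 or self.background_sd <= 0:
            raise ValidationError("scales and noise sigmas must be positive")
        n_background = int(round(self.n_genes * self.background_fraction))
        n_comm_genes = self.n_genes - n_background
        if n_comm_genes < 2 * self.n_communities:
            raise ValidationError(
                "too few non-background genes for the requested communities"
            )
        if self.n_regions < 2 * self.n_region_modules:
            raise ValidationError(
                "too few regions for the requested region modules"
            )


@dataclass
class GroundTruth:
    gene_to_community: dict  # background genes labeled BACKGROUND
    region_to_module: dict
    community_profiles: np.ndarray  # communities x regions, positive


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one expression matrix and its ground truth, reproducibly."""
    rng = np.random.default_rng(config.seed)
    n_background = int(round(config.n_genes * config.background_fraction))
    n_comm_genes = config.n_genes - n_background
    n_regions = config.n_regions

    # even split of regions into modules (leftover regions go to the last)
    module_of_region = np.repeat(
        np.arange(config.n_region_modules),
        np.diff(np.linspace(0, n_regions, config.n_region_modules + 1).astype(int)),
    )

    # community profiles: per module a gamma level, shared by the module's
    # regions up to 10% multiplicative jitter
    profiles = np.empty((config.n_communities, n_regions))
    for k in range(config.n_communities):
        levels = rng.gamma(shape=2.0, scale=config.profile_scale,
                           size=config.n_region_modules)
        base = levels[module_of_region]
        jitter = np.exp(rng.normal(0.0, 0.1, size=n_regions))
        profiles[k] = base * jitter

    # community gene assignment: as even as possible
    comm_sizes = np.diff(
        np.linspace(0, n_comm_genes, config.n_communities + 1).astype(int)
    )
    gene_comm = np.repeat(np.arange(config.n_communities), comm_sizes)

    values = np.empty((config.n_genes, n_regions))
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    gene_to_community: dict = {}

    # community genes: base level (log-uniform over one decade) times the
    # community profile times multiplicative log-normal noise
    base_levels = 10.0 ** rng.uniform(0.0, 1.0, size=n_comm_genes)
    noise = np.exp(rng.normal(0.0, config.noise_sd,
                              size=(n_comm_genes, n_regions)))
    values[:n_comm_genes] = (
        base_levels[:, None] * profiles[gene_comm] * noise
    )
    for i in range(n_comm_genes):
        gene_to_community[gene_ids[i]] = f"c{gene_comm[i] + 1}"

    # background genes: flat across regions at a shared constant level (the
    # mean of the community profile distribution) with small multiplicative
    # noise, so they form one tight low-variance population
    bg_level = 2.0 * config.profile_scale
    bg_noise = np.exp(rng.normal(0.0, config.background_sd,
                                 size=(n_background, n_regions)))
    values[n_comm_genes:] = bg_level * bg_noise
    for i in range(n_comm_genes, config.n_genes):
        gene_to_community[gene_ids[i]] = BACKGROUND

    region_labels = [f"r{j:03d}" for j in range(n_regions)]
    region_to_module = {
        region_labels[j]: f"m{module_of_region[j] + 1}" for j in range(n_regions)
    }
    expr = ExpressionMatrix(gene_ids, region_labels, values)
    truth = GroundTruth(gene_to_community, region_to_module, profiles)
    logger.info(
        "synthetic matrix: %d genes (%d background) x %d regions, "
        "%d communities, %d region modules",
        config.n_genes, n_background, n_regions,
        config.n_communities, config.n_region_modules,
    )
    return expr, truth


def generate_planted_multiplex(
    n_regions: int = 60,
    n_layers: int = 4,
    n_modules: int = 3,
    p_in: float = 0.6,
    p_out: float = 0.05,
    omega: float = 1.0,
    seed: int = 0,
) -> tuple[MultiplexNetwork, dict]:
    """Multiplex with the same region-module block pattern in every layer.

    Each layer is an independent planted-partition draw: region pairs inside
    a module are linked with probability ``p_in``, across modules ``p_out``.
    Returns the network and the region -> module ground truth.
    """
    rng = np.random.default_rng(seed)
    module_of_region = np.repeat(
        np.arange(n_modules),
        np.diff(np.linspace(0, n_regions, n_modules + 1).astype(int)),
    )
    same = module_of_region[:, None] == module_of_region[None, :]
    mats = []
    for _ in range(n_layers):
        p = np.where(same, p_in, p_out)
        draw = rng.random((n_regions, n_regions))
        a = np.triu(draw < p, k=1).astype(float)
        a = a + a.T
        mats.append(a)
    regions = [f"r{j:03d}" for j in range(n_regions)]
    layers = [f"L{s + 1}" for s in range(n_layers)]
    truth = {regions[j]: f"m{module_of_region[j] + 1}" for j in range(n_regions)}
    return MultiplexNetwork(regions, layers, mats, omega=omega), truth


def evaluate_recovery(estimated, truth) -> tuple[float, float]:
    """NMI and ARI between two labelings over the same items.

    Accepts two equal-length sequences, or two dicts over the same keys.
    Both scores are permutation-invariant; NMI of a constant labeling is 0.
    """
    if isinstance(estimated, dict) and isinstance(truth, dict):
        if set(estimated) != set(truth):
            raise ValidationError("labelings cover different items")
        keys = sorted(estimated)
        est = [estimated[k] for k in keys]
        tru = [truth[k] for k in keys]
    else:
        est = list(estimated)
        tru = list(truth)
        if len(est) != len(tru):
            raise ValidationError("labelings differ in length")
    est_codes = np.unique(np.asarray(est, dtype=str), return_inverse=True)[1]
    tru_codes = np.unique(np.asarray(tru, dtype=str), return_inverse=True)[1]
    nmi = float(normalized_mutual_info_score(tru_codes, est_codes))
    ari = float(adjusted_rand_score(tru_codes, est_codes))
    return nmi, ari
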