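"""Loading, blacklist filtering and variance-based screening of expression matrices.

The pipeline starts from a nonnegative genes x brain-regions expression
matrix.  Genes whose expression barely varies across regions carry little
information about regional connectivity, so a log10-variance threshold is
selected by sweeping candidate cutoffs and looking at the shape of the
retained-gene curve: the cutoff sits where the curve drops fastest (first
derivative minimal) and flattens out right after (second derivative maximal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "VarianceTable",
    "ThresholdSweep",
    "load_expression",
    "load_blacklist",
    "filter_blacklist",
    "gene_log_variance",
    "sweep_variance_threshold",
    "variant_gene_ids",
]


class ValidationError(ValueError):
    """Raised when an input matrix violates its contract."""


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values, genes as rows and brain regions as columns."""

    gene_ids: list[str]
    region_labels: list[str]
    values: np.ndarray  # shape (n_genes, n_regions), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.region_labels) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.region_labels)} region labels for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id {dup!r}")
        if len(set(self.region_labels)) != len(self.region_labels):
            dup = _first_duplicate(self.region_labels)
            raise ValidationError(f"duplicate region label {dup!r}")
        if self.values.shape[1] < 2:
            raise ValidationError("need at least 2 regions")
        if np.isnan(self.values).any():
            raise ValidationError("missing values in expression matrix")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, region {self.region_labels[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            region_labels=[str(r) for r in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.region_labels
        )

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row-subset preserving the given order; unknown ids raise KeyError."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.region_labels),
                                self.values[idx])

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t")


@dataclass
class VarianceTable:
    """Per-gene log10 of the (N-1)-denominator sample variance across regions.

    Zero-variance genes get a -inf sentinel and ``finite_mask`` False; they are
    never classified as variant.
    """

    gene_ids: list[str]
    log_variance: np.ndarray
    finite_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"log10_variance": self.log_variance, "finite": self.finite_mask},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


@dataclass
class ThresholdSweep:
    """Retained-gene curve over a grid of log-variance cutoffs.

    ``first_derivative`` / ``second_derivative`` are central finite differences,
    NaN at the two boundary grid points.
    """

    grid: np.ndarray
    retained_counts: np.ndarray
    first_derivative: np.ndarray
    second_derivative: np.ndarray
    selected_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.grid,
                "retained": self.retained_counts,
                "d1": self.first_derivative,
                "d2": self.second_derivative,
            }
        )


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def load_expression(path) -> ExpressionMatrix:
    """Read a TSV with a header row of region labels and gene ids in column 1.

    Rows containing missing values are dropped (count logged); duplicate gene
    ids or negative values abort with a :class:`ValidationError`.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise ValidationError(f"cannot parse expression matrix {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ValidationError(f"no region columns found in {path}")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression value in {path}: {exc}") from exc
    n_missing = int(np.isnan(values).any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d rows with missing values", n_missing)
        keep = ~np.isnan(values).any(axis=1)
        frame = frame.loc[keep]
    return ExpressionMatrix.from_frame(frame)


def load_blacklist(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    ids: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return ids


def filter_blacklist(expr: ExpressionMatrix, blacklist: set[str]) -> ExpressionMatrix:
    """Drop blacklisted genes (e.g. transcription/translation machinery).

    Row order of the survivors is preserved; blacklist entries absent from the
    matrix are ignored.
    """
    blacklist = set(blacklist)
    missing = blacklist.difference(expr.gene_ids)
    if missing:
        logger.debug("%d blacklist entries not present in matrix", len(missing))
    keep = [g for g in expr.gene_ids if g not in blacklist]
    removed = expr.n_genes - len(keep)
    logger.info("blacklist removed %d of %d genes", removed, expr.n_genes)
    if removed == 0:
        return expr
    return expr.subset(keep)


def gene_log_variance(expr: ExpressionMatrix) -> VarianceTable:
    """log10 of each gene's sample variance (ddof=1) across brain regions."""
    if expr.n_regions < 2:
        raise ValidationError("variance needs at least 2 regions")
    var = expr.values.var(axis=1, ddof=1)
    finite = var > 0
    logvar = np.full(expr.n_genes, -np.inf)
    logvar[finite] = np.log10(var[finite])
    return VarianceTable(list(expr.gene_ids), logvar, finite)


def sweep_variance_threshold(vt: VarianceTable, step: float = 0.1) -> ThresholdSweep:
    """Pick the variant-gene cutoff from the retained-count curve.

    The grid runs from floor(min finite log-variance) to ceil(max) in ``step``
    increments.  The cutoff must satisfy two conditions at once: the retained
    curve drops fastest (first derivative minimal) and flattens right after
    (second derivative maximal).  On a discrete curve these rarely coincide
    exactly, so candidates are the interior grid points descending at least
    half as fast as the steepest descent, and among those the largest central
    second difference wins — placing the cutoff at the foot of the drop.
    Ties go to the smallest cutoff.  Genes with log-variance strictly above
    the winner are "variant".
    """
    if step <= 0:
        raise ValueError("step must be positive")
    finite_vals = vt.log_variance[vt.finite_mask]
    if finite_vals.size == 0:
        raise ValidationError("no gene has positive variance")
    lo, hi = finite_vals.min(), finite_vals.max()
    if lo == hi:
        raise ValidationError("all log-variances equal; no sweep possible")
    grid = np.arange(math.floor(lo), math.ceil(hi) + step / 2, step)
    if grid.size < 3:
        raise ValidationError("grid spans fewer than 3 points")
    sorted_vals = np.sort(finite_vals)
    # retained = number of genes with log-variance strictly above the cutoff
    retained = sorted_vals.size - np.searchsorted(sorted_vals, grid, side="right")
    retained = retained.astype(float)

    d1 = np.full(grid.size, np.nan)
    d2 = np.full(grid.size, np.nan)
    h = step
    d1[1:-1] = (retained[2:] - retained[:-2]) / (2 * h)
    d2[1:-1] = (retained[2:] - 2 * retained[1:-1] + retained[:-2]) / h**2

    interior = np.arange(1, grid.size - 1)
    d1_min = np.nanmin(d1[interior])
    # "at least half as steep as the steepest descent"; falls back to exact
    # ties when the curve is flat (d1_min == 0 cannot occur: counts strictly
    # decrease somewhere since not all log-variances are equal)
    candidates = interior[d1[interior] <= 0.5 * d1_min + 1e-9]
    best = candidates[np.argmax(d2[candidates])]  # first argmax -> smallest cutoff
    selected = float(grid[best])
    logger.info(
        "variance sweep selected threshold %.3f (%d of %d genes variant)",
        selected, int((vt.log_variance > selected).sum()), len(vt.gene_ids),
    )
    return ThresholdSweep(grid, retained, d1, d2, selected)


def variant_gene_ids(vt: VarianceTable, threshold: float) -> list[str]:
    """Gene ids with finite log-variance strictly above the cutoff."""
    mask = vt.finite_mask & (vt.log_variance > threshold)
    return [g for g, m in zip(vt.gene_ids, mask) if m]
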