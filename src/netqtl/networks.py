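"""Per-genotype correlation networks and the 3-slide differential tensor.

At a marker, samples are grouped by genotype; each group yields a Pearson
correlation matrix over genes.  Within-chromosome entries (and the diagonal)
can be masked to zero so the analysis focuses on cross-chromosome
co-expression.  The three pairwise differences are stacked, in order
(B-A, H-A, H-B), into a p x p x 3 tensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from netqtl.io_model import (
    GENO_A,
    GENO_B,
    GENO_H,
    ExpressionMatrix,
    GeneMap,
    GenotypeMatrix,
    ProcessingState,
)

logger = logging.getLogger(__name__)

#: slide order of the differential tensor
SLIDE_ORDER = ("AB", "AH", "BH")


@dataclass
class GenotypeGroups:
    """Sample ids partitioned by genotype at one marker."""

    marker_id: str
    samples_a: list[str]
    samples_h: list[str]
    samples_b: list[str]
    min_group: int = 1

    @property
    def n_a(self) -> int:
        return len(self.samples_a)

    @property
    def n_h(self) -> int:
        return len(self.samples_h)

    @property
    def n_b(self) -> int:
        return len(self.samples_b)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_a, self.n_h, self.n_b)

    def nonempty(self) -> list[tuple[str, list[str]]]:
        """(genotype, samples) for each non-empty group, in A, H, B order."""
        pairs = [("A", self.samples_a), ("H", self.samples_h), ("B", self.samples_b)]
        return [(g, s) for g, s in pairs if s]

    @property
    def testable(self) -> bool:
        return len(self.nonempty()) >= 2

    @property
    def has_small_group(self) -> bool:
        return any(len(s) < self.min_group for _, s in self.nonempty())


def group_by_genotype(
    geno: GenotypeMatrix, marker_id: str, min_group: int = 10
) -> GenotypeGroups:
    """Partition samples by genotype code at a marker; missing calls join no group."""
    row = geno.codes[geno.marker_index(marker_id)]
    ids = np.asarray(geno.sample_ids, dtype=object)
    groups = GenotypeGroups(
        marker_id=marker_id,
        samples_a=list(ids[row == GENO_A]),
        samples_h=list(ids[row == GENO_H]),
        samples_b=list(ids[row == GENO_B]),
        min_group=min_group,
    )
    if not groups.testable:
        logger.warning("marker %s: fewer than 2 non-empty genotype groups", marker_id)
    elif groups.has_small_group:
        logger.warning(
            "marker %s: genotype group below min_group=%d (sizes %s)",
            marker_id,
            min_group,
            groups.counts,
        )
    return groups


def pearson_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation over columns of a genes x samples block.

    Returns (matrix, zero_variance_mask).  Genes with zero variance in the
    block get correlation 0 to all genes (including themselves).
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    zero_var = norms <= 0
    safe = np.where(zero_var, 1.0, norms)
    z = centered / safe[:, None]
    corr = z @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    if zero_var.any():
        corr[zero_var, :] = 0.0
        corr[:, zero_var] = 0.0
    else:
        np.fill_diagonal(corr, 1.0)
    if zero_var.any():
        # restore unit diagonal for genes that do vary
        d = np.where(zero_var, 0.0, 1.0)
        corr[np.arange(len(d)), np.arange(len(d))] = d
    return corr, zero_var


@dataclass
class CorrelationNetwork:
    """Symmetric gene-gene Pearson correlation matrix for one genotype group."""

    matrix: np.ndarray
    gene_ids: list[str]
    genotype: str | None = None
    masked: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.gene_ids)
        if self.matrix.shape != (p, p):
            raise ValueError("correlation matrix shape does not match gene ids")
        if np.abs(self.matrix - self.matrix.T).max(initial=0.0) > 1e-10:
            raise ValueError("correlation matrix must be symmetric")
        if self.matrix.size and (np.abs(self.matrix) > 1 + 1e-10).any():
            raise ValueError("correlation entries must lie in [-1, 1]")


def correlation_network(
    expr: ExpressionMatrix, samples: list[str], genotype: str | None = None
) -> CorrelationNetwork:
    """Pearson correlation network over the given samples.

    Requires at least 2 samples; residualized input is expected (raw counts
    trigger a warning, not an error, so exploratory use stays possible).
    """
    if len(samples) < 2:
        raise ValueError(f"need >= 2 samples to correlate, got {len(samples)}")
    if expr.state is ProcessingState.RAW_COUNTS:
        logger.warning("correlation_network called on raw counts; preprocess first")
    idx = expr.sample_index(samples)
    corr, zero_var = pearson_matrix(expr.values[:, idx])
    if zero_var.any():
        names = [expr.gene_ids[j] for j in np.flatnonzero(zero_var)[:5]]
        logger.warning(
            "%d gene(s) with zero variance in group set to correlation 0 (e.g. %s)",
            int(zero_var.sum()),
            names,
        )
    return CorrelationNetwork(corr, list(expr.gene_ids), genotype=genotype, masked=False)


def same_chromosome_mask(gene_ids: list[str], gmap: GeneMap) -> np.ndarray:
    """Boolean p x p matrix, True where two genes share a chromosome (incl. diagonal)."""
    chrom = gmap.chrom_of(gene_ids)
    return chrom[:, None] == chrom[None, :]


def mask_within_chromosome(net: CorrelationNetwork, gmap: GeneMap) -> CorrelationNetwork:
    """Zero all same-chromosome entries (and the diagonal) of a correlation network."""
    if net.masked:
        raise ValueError("network is already masked")
    mask = same_chromosome_mask(net.gene_ids, gmap)
    out = net.matrix.copy()
    out[mask] = 0.0
    return CorrelationNetwork(out, list(net.gene_ids), genotype=net.genotype, masked=True)


@dataclass
class DifferentialTensor:
    """p x p x 3 stack of pairwise differential correlation matrices.

    Slides are ordered (AB, AH, BH) = (N_B - N_A, N_H - N_A, N_H - N_B), so
    slide BH always equals slide AH minus slide AB.
    """

    slides: np.ndarray
    gene_ids: list[str]
    marker_id: str = ""

    def __post_init__(self) -> None:
        self.slides = np.asarray(self.slides, dtype=float)
        p = len(self.gene_ids)
        if self.slides.shape != (p, p, 3):
            raise ValueError(f"tensor shape {self.slides.shape} != ({p}, {p}, 3)")
        for l in range(3):
            s = self.slides[:, :, l]
            if np.abs(s - s.T).max(initial=0.0) > 1e-8:
                raise ValueError(f"slide {SLIDE_ORDER[l]} is not symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def slide(self, name: str) -> np.ndarray:
        return self.slides[:, :, SLIDE_ORDER.index(name)]


def differential_tensor(
    n_a: CorrelationNetwork,
    n_h: CorrelationNetwork,
    n_b: CorrelationNetwork,
    marker_id: str = "",
) -> DifferentialTensor:
    """Stack the three pairwise network differences into a tensor."""
    nets = (n_a, n_h, n_b)
    gene_ids = n_a.gene_ids
    for net in nets[1:]:
        if net.gene_ids != gene_ids:
            raise ValueError("correlation networks have different gene ids/order")
    if len({net.masked for net in nets}) != 1:
        raise ValueError("correlation networks are inconsistently masked")
    slides = np.stack(
        [
            n_b.matrix - n_a.matrix,
            n_h.matrix - n_a.matrix,
            n_h.matrix - n_b.matrix,
        ],
        axis=2,
    )
    return DifferentialTensor(slides, list(gene_ids), marker_id=marker_id)
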