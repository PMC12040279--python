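"""Test statistics, permutation p-values, the two-stage genome scan, and the
local F-test baseline.

The permutation null at a marker is obtained by reshuffling genotype labels
over the pooled (non-missing) samples while preserving the observed group
sizes, then re-running the whole network pipeline (grouping, correlation,
masking, tensor, statistic).  Empirical p-values follow the plain counting
formula p = (1/B) sum I{S_b >= S}; an optional (1 + count) / (1 + B)
correction is available but off by default.

Per-marker random streams are keyed by (master seed, marker index, stage) so
results never depend on marker iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from netqtl.io_model import ExpressionMatrix, GeneMap, GenotypeMatrix
from netqtl.networks import (
    GenotypeGroups,
    group_by_genotype,
    pearson_matrix,
    same_chromosome_mask,
)
from netqtl.spectral import pmd_sparse_eigen, sstd

logger = logging.getLogger(__name__)

STATISTICS = ("tensor", "max", "sum", "tensor_sq")


@dataclass
class ScanConfig:
    """Settings for a genome scan.

    ``B0`` permutations are used for screening every marker; markers whose
    screening p-value falls below ``alpha_screen`` are re-tested with ``B``
    permutations.  ``R=None`` means non-sparse (R = p).
    """

    statistic: str = "tensor"
    R: int | None = None
    B0: int = 100
    B: int = 500
    alpha_screen: float = 0.05
    seed: int = 0
    min_group: int = 10
    mask: bool = True
    restarts: int = 2
    T: int = 30
    plus_one: bool = False
    skip_small: bool = True
    screen_only: bool = False

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}; choose from {STATISTICS}")
        if self.B0 < 1 or self.B < 1:
            raise ValueError("permutation counts B0, B must be >= 1")
        if not 0.0 < self.alpha_screen < 1.0:
            raise ValueError("alpha_screen must lie in (0, 1)")


# ---------------------------------------------------------------------------
# statistics on a differential tensor

def _slides_of(D) -> np.ndarray:
    return np.asarray(getattr(D, "slides", D), dtype=float)


def stat_tensor(D, R=None, seed: int = 0, restarts: int = 5, T: int = 50) -> float:
    """Sparse leading tensor eigenvalue of the differential tensor."""
    slides = _slides_of(D)
    if R is None:
        R = slides.shape[0]
    return sstd(slides, R, T=T, restarts=restarts, seed=seed).Lambda


def stat_tensor_sq(D, R=None, seed: int = 0, restarts: int = 5, T: int = 50) -> float:
    """Squared sparse leading tensor eigenvalue."""
    return stat_tensor(D, R, seed=seed, restarts=restarts, T=T) ** 2


def _slide_slmes(D, R=None) -> list[float]:
    slides = _slides_of(D)
    if R is None:
        R = slides.shape[0]
    return [pmd_sparse_eigen(slides[:, :, l], R).lambda_ for l in range(slides.shape[2])]


def stat_max(D, R=None, seed: int = 0) -> float:
    """Maximal sparse leading matrix eigenvalue over the three slides."""
    return max(_slide_slmes(D, R))


def stat_sum(D, R=None, seed: int = 0) -> float:
    """Sum of the three slide-wise sparse leading matrix eigenvalues."""
    return float(sum(_slide_slmes(D, R)))


def empirical_pvalue(S: float, perm_stats, plus_one: bool = False) -> tuple[float, int]:
    """Counting p-value from permuted statistics: (p, exceed_count)."""
    perm_stats = np.asarray(perm_stats, dtype=float)
    B = perm_stats.size
    if B < 1:
        raise ValueError("need at least one permutation statistic")
    exceed = int((perm_stats >= S).sum())
    p = (1 + exceed) / (1 + B) if plus_one else exceed / B
    return p, exceed


# ---------------------------------------------------------------------------
# fast per-assignment statistic evaluation

class _MarkerEngine:
    """Recomputes the pipeline statistic for arbitrary group assignments.

    Holds the expression values, the (optional) same-chromosome mask, and the
    scan configuration; used for both the observed grouping and every
    permutation at a marker.
    """

    def __init__(self, expr: ExpressionMatrix, gmap: GeneMap | None, cfg: ScanConfig):
        self.values = expr.values
        self.cfg = cfg
        p = expr.n_genes
        self.R = cfg.R if cfg.R is not None else p
        if not 1 <= self.R <= p:
            raise ValueError(f"sparsity R={self.R} out of range [1, {p}]")
        self.mask = None
        if cfg.mask:
            if gmap is None:
                raise ValueError("masking requested but no gene map given")
            self.mask = same_chromosome_mask(expr.gene_ids, gmap)

    def _corr(self, cols: np.ndarray) -> np.ndarray:
        corr, _ = pearson_matrix(self.values[:, cols])
        if self.mask is not None:
            corr[self.mask] = 0.0
        return corr

    def statistic(self, group_cols: list[np.ndarray], stat_seed: int) -> float:
        """Statistic for an assignment given as per-group column indices (A, H, B order,
        empty groups omitted)."""
        cfg = self.cfg
        mats = [self._corr(cols) for cols in group_cols]
        if len(mats) == 3:
            n_a, n_h, n_b = mats
            slides = np.stack([n_b - n_a, n_h - n_a, n_h - n_b], axis=2)
            if cfg.statistic == "tensor":
                return stat_tensor(slides, self.R, seed=stat_seed, restarts=cfg.restarts, T=cfg.T)
            if cfg.statistic == "tensor_sq":
                return stat_tensor_sq(slides, self.R, seed=stat_seed, restarts=cfg.restarts, T=cfg.T)
            if cfg.statistic == "max":
                return stat_max(slides, self.R)
            return stat_sum(slides, self.R)
        if len(mats) == 2:
            # two-genotype marker: single pairwise difference, matrix statistics
            diff = mats[1] - mats[0]
            lam = pmd_sparse_eigen(diff, self.R).lambda_
            if cfg.statistic == "tensor_sq":
                return lam**2
            return lam
        raise ValueError("need 2 or 3 non-empty genotype groups")


def _group_columns(expr: ExpressionMatrix, groups: GenotypeGroups) -> list[np.ndarray]:
    return [expr.sample_index(s) for _, s in groups.nonempty()]


def permutation_pvalue(
    expr: ExpressionMatrix,
    groups: GenotypeGroups,
    cfg: ScanConfig,
    B_use: int,
    gmap: GeneMap | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, int]:
    """Observed statistic plus permutation p-value at one marker.

    Returns (S, p_value, exceed_count).  Labels are reshuffled over the
    pooled grouped samples, preserving group sizes; the full pipeline is
    recomputed per permutation.
    """
    if B_use < 1:
        raise ValueError("need at least one permutation")
    if not groups.testable:
        raise ValueError(f"marker {groups.marker_id!r} is untestable (<2 groups)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    engine = _MarkerEngine(expr, gmap, cfg)
    group_cols = _group_columns(expr, groups)
    S = engine.statistic(group_cols, stat_seed=cfg.seed)

    pooled = np.concatenate(group_cols)
    sizes = [len(c) for c in group_cols]
    bounds = np.cumsum(sizes)[:-1]
    perm_stats = np.empty(B_use)
    for b in range(B_use):
        shuffled = rng.permutation(pooled)
        perm_cols = np.split(shuffled, bounds)
        perm_stats[b] = engine.statistic(perm_cols, stat_seed=cfg.seed)
    p, exceed = empirical_pvalue(S, perm_stats, plus_one=cfg.plus_one)
    return S, p, exceed


# ---------------------------------------------------------------------------
# genome scan

@dataclass
class ScanResult:
    """Per-marker scan output; ``table`` is the Manhattan-ready frame."""

    table: pd.DataFrame
    config: ScanConfig

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    gmap: GeneMap | None,
    cfg: ScanConfig,
) -> ScanResult:
    """Two-stage permutation scan over all markers.

    Stage 1 screens every testable marker with ``cfg.B0`` permutations;
    markers with screening p-value below ``cfg.alpha_screen`` are confirmed
    with ``cfg.B`` permutations.  Deterministic for a fixed seed and
    independent of marker order.
    """
    if geno.sample_ids != expr.sample_ids:
        geno = geno.reorder_samples(expr.sample_ids)
    rows = []
    for idx, marker_id in enumerate(geno.marker_ids):
        chrom = int(geno.chrom[idx]) if geno.chrom is not None else 0
        pos = int(geno.pos[idx]) if geno.pos is not None else idx + 1
        groups = group_by_genotype(geno, marker_id, min_group=cfg.min_group)
        row = {
            "marker_id": marker_id,
            "chrom": chrom,
            "pos": pos,
            "n_a": groups.n_a,
            "n_h": groups.n_h,
            "n_b": groups.n_b,
            "statistic": np.nan,
            "p_value": np.nan,
            "p_screen": np.nan,
            "exceed_count": -1,
            "B_used": 0,
            "stage": "untestable",
        }
        untestable = not groups.testable or (cfg.skip_small and groups.has_small_group)
        if untestable:
            rows.append(row)
            continue
        rng1 = np.random.default_rng([cfg.seed, idx, 1])
        S, p1, exceed1 = permutation_pvalue(expr, groups, cfg, cfg.B0, gmap=gmap, rng=rng1)
        row.update(statistic=S, p_screen=p1, p_value=p1, exceed_count=exceed1, B_used=cfg.B0)
        if p1 < cfg.alpha_screen and not cfg.screen_only:
            rng2 = np.random.default_rng([cfg.seed, idx, 2])
            S2, p2, exceed2 = permutation_pvalue(expr, groups, cfg, cfg.B, gmap=gmap, rng=rng2)
            row.update(statistic=S2, p_value=p2, exceed_count=exceed2, B_used=cfg.B, stage="confirmed")
        else:
            row["stage"] = "screened_out"
        rows.append(row)
    table = pd.DataFrame(rows)
    n_tested = int((table["stage"] != "untestable").sum())
    logger.info("scan: %d/%d markers tested", n_tested, len(table))
    return ScanResult(table=table, config=cfg)


# ---------------------------------------------------------------------------
# local baseline: pairwise co-expression F-tests

def baseline_local_test(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    gmap: GeneMap | None,
    marker_id: str,
) -> float:
    """Marker-level p-value from per-pair co-expression regressions.

    For every cross-chromosome gene pair, the per-sample product of the two
    genes' standardized residual expressions is regressed on genotype dosage
    (A=0, H=1, B=2); slope F-test p-values are combined into one marker-level
    p by Bonferroni-adjusted minimum.  Returns NaN when the marker has a
    single genotype class (untestable).
    """
    if geno.sample_ids != expr.sample_ids:
        geno = geno.reorder_samples(expr.sample_ids)
    row = geno.codes[geno.marker_index(marker_id)]
    keep = row >= 0
    dosage = row[keep].astype(float)
    if np.unique(dosage).size < 2:
        logger.warning("baseline: marker %s has a single genotype class", marker_id)
        return float("nan")
    X = expr.values[:, keep]
    n = X.shape[1]
    if n < 3:
        return float("nan")

    centered = X - X.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    ok_gene = sd > 0
    z = np.where(ok_gene[:, None], centered / np.where(ok_gene, sd, 1.0)[:, None], 0.0)

    # proxy_jk = z_j * z_k per sample; correlate every pair with dosage
    d = dosage - dosage.mean()
    d_norm = np.linalg.norm(d)
    prod = z[:, None, :] * z[None, :, :]  # (p, p, n)
    prod_c = prod - prod.mean(axis=2, keepdims=True)
    num = prod_c @ d
    den = np.sqrt((prod_c * prod_c).sum(axis=2)) * d_norm
    valid = (den > 0) & ok_gene[:, None] & ok_gene[None, :]

    p_genes = X.shape[0]
    iu, ju = np.triu_indices(p_genes, k=1)
    if gmap is not None:
        chrom = gmap.chrom_of(expr.gene_ids)
        cross = chrom[iu] != chrom[ju]
    else:
        cross = np.ones(iu.size, dtype=bool)
    use = cross & valid[iu, ju]
    n_pairs = int(use.sum())
    if n_pairs == 0:
        return float("nan")
    r = num[iu[use], ju[use]] / den[iu[use], ju[use]]
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    fstat = (n - 2) * r**2 / (1 - r**2)
    pair_p = sps.f.sf(fstat, 1, n - 2)
    return float(min(1.0, n_pairs * pair_p.min()))
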