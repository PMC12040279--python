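"""Synthetic F2-intercross data with a planted network-effect locus.

Genotypes: two divergent homozygous parents (all-A x all-B) are crossed; the
F1 is uniformly heterozygous; each F2 individual receives two F1 gametes,
each gamete carrying exactly one crossover per chromosome at a uniform
position.  Adjacent markers on a chromosome are therefore correlated (LD
blocks) while markers on different chromosomes are independent.

Expression: read counts are Poisson with log-rate
``mu_j + d_i * effect_size * f_i * s_j`` where ``d_i`` in {0, 1/2, 1} is the
individual's scaled dosage at the planted locus, ``f_i`` a per-individual
latent factor and ``s_j`` per-gene loadings.  The shared factor induces
cross-gene correlation whose strength grows additively with dosage, so the
planted marker modulates the co-expression network of all genes; with
``effect_size = 0`` counts are independent Poisson draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netqtl.io_model import ExpressionMatrix, GeneMap, GenotypeMatrix, ProcessingState

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the synthetic cross + expression generator."""

    n: int = 300
    n_genes: int = 200
    n_chrom: int = 20
    snqtl_index: int | None = None  # planted marker/gene index; None -> random
    effect_size: float = 1.0
    baseline_mean: float = 20.0
    mu_sd: float = 0.3  # per-gene spread of baseline log-rates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.n_genes % self.n_chrom != 0:
            raise ValueError(
                f"n_genes={self.n_genes} not divisible by n_chrom={self.n_chrom}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.snqtl_index is not None and not 0 <= self.snqtl_index < self.n_genes:
            raise ValueError("snqtl_index out of range")

    @property
    def markers_per_chrom(self) -> int:
        return self.n_genes // self.n_chrom


def _marker_positions(cfg: SimConfig) -> np.ndarray:
    """Relative positions in (0, 1) of markers along one chromosome."""
    m = cfg.markers_per_chrom
    return (np.arange(m) + 1.0) / (m + 1.0)


def simulate_cross(cfg: SimConfig) -> GenotypeMatrix:
    """F2 genotypes at evenly spaced markers, one per candidate gene.

    Each gamete starts on a random parental haplotype and switches at one
    uniform crossover point; the genotype is the unordered pair of inherited
    alleles (0 A alleles -> A, 1 -> H, 2 -> B).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    pos = _marker_positions(cfg)
    m = cfg.markers_per_chrom
    blocks = []
    for _ in range(cfg.n_chrom):
        xo = rng.uniform(size=(cfg.n, 2))  # crossover point per individual x gamete
        start = rng.integers(0, 2, size=(cfg.n, 2))  # starting haplotype (0=A, 1=B)
        allele = np.where(pos[None, None, :] < xo[:, :, None], start[:, :, None], 1 - start[:, :, None])
        blocks.append(allele.sum(axis=1))  # dosage of B alleles, (n, m)
    dosage = np.concatenate(blocks, axis=1).T  # (markers, n)
    codes = dosage.astype(np.int8)  # 0 -> A, 1 -> H, 2 -> B matches internal coding
    marker_ids = [f"M{i + 1:04d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n)]
    chrom = np.repeat(np.arange(1, cfg.n_chrom + 1), m)
    posn = np.tile(np.arange(1, m + 1), cfg.n_chrom)
    return GenotypeMatrix(codes, marker_ids, sample_ids, chrom=chrom, pos=posn)


def _effect_params(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, np.ndarray]:
    if cfg.snqtl_index is None:
        planted = int(rng.integers(0, cfg.n_genes))
    else:
        planted = cfg.snqtl_index
    # every gene carries a bounded-away-from-zero loading so all are affected
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    s = signs * rng.uniform(0.5, 1.0, size=cfg.n_genes)
    return planted, s


def simulate_expression(geno: GenotypeMatrix, cfg: SimConfig) -> ExpressionMatrix:
    """Poisson counts whose co-expression depends on genotype at the planted locus."""
    rng = np.random.default_rng([cfg.seed, 2])
    planted, s = _effect_params(cfg, rng)
    mu = np.log(cfg.baseline_mean) + rng.normal(0.0, cfg.mu_sd, size=cfg.n_genes)
    f = rng.standard_normal(geno.n_samples)
    d = geno.codes[planted].astype(float) / 2.0  # {0, 1/2, 1}; simulated data has no NA
    log_rate = mu[:, None] + cfg.effect_size * (d * f)[None, :] * s[:, None]
    counts = rng.poisson(np.exp(log_rate)).astype(float)
    gene_ids = [f"G{j + 1:04d}" for j in range(cfg.n_genes)]
    return ExpressionMatrix(counts, gene_ids, list(geno.sample_ids), ProcessingState.RAW_COUNTS)


def gene_map_for(cfg: SimConfig) -> GeneMap:
    """Gene map co-locating gene j with marker j (evenly spaced per chromosome)."""
    m = cfg.markers_per_chrom
    table = pd.DataFrame(
        {
            "gene_id": [f"G{j + 1:04d}" for j in range(cfg.n_genes)],
            "chrom": np.repeat(np.arange(1, cfg.n_chrom + 1), m),
            "pos": np.tile(np.arange(1, m + 1), cfg.n_chrom),
        }
    ).set_index("gene_id")
    return GeneMap(table)


def simulate_dataset(
    cfg: SimConfig, outdir: str | Path | None = None
) -> tuple[ExpressionMatrix, GenotypeMatrix, GeneMap, dict]:
    """Full synthetic dataset plus ground truth; optionally written as TSVs.

    Returns (expression, genotypes, gene map, truth) where ``truth`` records
    the planted marker and the generator's effect parameters.
    """
    geno = simulate_cross(cfg)
    expr = simulate_expression(geno, cfg)
    gmap = gene_map_for(cfg)
    # re-derive the planted index from the same stream used by simulate_expression
    rng = np.random.default_rng([cfg.seed, 2])
    planted, s = _effect_params(cfg, rng)
    truth = {
        "planted_marker": geno.marker_ids[planted],
        "planted_index": planted,
        "effect_size": cfg.effect_size,
        "baseline_mean": cfg.baseline_mean,
        "gene_loadings": s.tolist(),
        "seed": cfg.seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        expr.to_tsv(outdir / "expression.tsv")
        geno.to_tsv(outdir / "genotypes.tsv")
        gmap.to_tsv(outdir / "genemap.tsv")
        pd.DataFrame(
            {"marker_id": geno.marker_ids, "chrom": geno.chrom, "pos": geno.pos}
        ).to_csv(outdir / "markermap.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
        logger.info("wrote synthetic dataset to %s", outdir)
    return expr, geno, gmap, truth
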