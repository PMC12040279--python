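"""Interpretable products of the rank-1 tensor fit at a marker.

Gene leverage is the element-wise square of the sparse eigenvector v (sums
to 1); the joint differential network is vv' restricted to the support of v;
each retained edge also carries the rank-1 reconstruction of its change in
every genotype comparison, Lambda * v_j * v_k * u_l, whose sign encodes
enhancement versus reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netqtl.networks import SLIDE_ORDER, CorrelationNetwork
from netqtl.spectral import SpectralResult

logger = logging.getLogger(__name__)


def leverage_scores(res: SpectralResult) -> np.ndarray:
    """Per-gene leverage v_j^2; sums to 1 for a unit eigenvector."""
    return res.v**2


def top_genes(leverage: np.ndarray, k: int, gene_ids: list[str]) -> pd.DataFrame:
    """Top-k genes by leverage with cumulative sums (ties broken by gene id)."""
    p = len(gene_ids)
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")
    order = sorted(range(p), key=lambda j: (-leverage[j], gene_ids[j]))[:k]
    lev = np.asarray(leverage, dtype=float)[order]
    return pd.DataFrame(
        {
            "gene_id": [gene_ids[j] for j in order],
            "leverage": lev,
            "rank": np.arange(1, k + 1),
            "cumulative_leverage": np.cumsum(lev),
        }
    )


@dataclass
class JointDifferentialNetwork:
    """Rank-1 summary of co-expression changes across genotypes at a marker."""

    gene_ids: list[str]
    leverage: np.ndarray
    edges: pd.DataFrame  # gene_j, gene_k, weight, change_ab, change_ah, change_bh
    Lambda: float
    u: np.ndarray
    degenerate: bool = False


def build_network(
    res: SpectralResult,
    gene_ids: list[str],
    top_fraction: float = 0.10,
) -> JointDifferentialNetwork:
    """Edge list among support genes, keeping the top fraction by |v_j * v_k|."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    lev = leverage_scores(res)
    columns = ["gene_j", "gene_k", "weight", "change_ab", "change_ah", "change_bh"]
    if res.Lambda == 0.0 or res.degenerate:
        logger.warning("degenerate spectral result (Lambda=0): empty network")
        return JointDifferentialNetwork(
            list(gene_ids), lev, pd.DataFrame(columns=columns), 0.0, res.u, degenerate=True
        )
    support = np.flatnonzero(res.v)
    iu, ju = np.triu_indices(len(support), k=1)
    gi, gj = support[iu], support[ju]
    weight = res.v[gi] * res.v[gj]
    order = np.argsort(-np.abs(weight), kind="stable")
    n_keep = max(1, int(np.ceil(top_fraction * len(order))))
    order = order[:n_keep]
    gi, gj, weight = gi[order], gj[order], weight[order]
    changes = res.Lambda * weight[:, None] * res.u[None, :]
    edges = pd.DataFrame(
        {
            "gene_j": [gene_ids[i] for i in gi],
            "gene_k": [gene_ids[j] for j in gj],
            "weight": weight,
            "change_ab": changes[:, 0],
            "change_ah": changes[:, 1],
            "change_bh": changes[:, 2],
        }
    )
    return JointDifferentialNetwork(list(gene_ids), lev, edges, res.Lambda, res.u)


def genotype_network_views(
    n_a: CorrelationNetwork,
    n_h: CorrelationNetwork,
    n_b: CorrelationNetwork,
    network: JointDifferentialNetwork,
) -> dict[str, pd.DataFrame]:
    """Raw within-genotype correlations for every retained edge.

    Returns one edge table per genotype ({"A", "H", "B"}), enabling the
    additive-effect visual check (monotone correlation across A, H, B).
    """
    nets = {"A": n_a, "H": n_h, "B": n_b}
    for net in nets.values():
        if net.gene_ids != network.gene_ids:
            raise ValueError("correlation network gene ids differ from the joint network")
    index = {g: j for j, g in enumerate(network.gene_ids)}
    ii = np.array([index[g] for g in network.edges["gene_j"]], dtype=int)
    jj = np.array([index[g] for g in network.edges["gene_k"]], dtype=int)
    out = {}
    for label, net in nets.items():
        out[label] = pd.DataFrame(
            {
                "gene_j": network.edges["gene_j"].to_numpy(),
                "gene_k": network.edges["gene_k"].to_numpy(),
                "correlation": net.matrix[ii, jj] if len(ii) else np.array([]),
            }
        )
    return out
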