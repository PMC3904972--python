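"""Phenotype-specific co-expression network inference.

Edges are significant Spearman rank correlations between gene pairs within
one phenotype group: rho is the Pearson correlation of mid-ranks, the
no-correlation p-value comes from the large-sample normal approximation
``z = rho * sqrt(m - 1)`` (valid for groups larger than 10 samples), and an
edge is called when ``p < alpha`` AND the Benjamini-Hochberg FDR over all
unordered pairs is below ``q`` (defaults 0.05 and 0.20).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io import ExpressionDataset
from .stats import bh_fdr

__all__ = [
    "CoexpressionNetwork",
    "CorrelationTestResult",
    "spearman_matrix",
    "correlation_pvalues",
    "call_edges",
    "infer_network",
    "DEFAULT_ALPHA",
    "DEFAULT_FDR_Q",
    "MIN_GROUP_SIZE",
]

DEFAULT_ALPHA = 0.05
DEFAULT_FDR_Q = 0.20
MIN_GROUP_SIZE = 11  # asymptotic Spearman test needs > 10 samples


@dataclass
class CoexpressionNetwork:
    """Undirected, unweighted co-expression graph as a binary adjacency."""

    adjacency: np.ndarray
    gene_ids: list[str]
    alpha: float | None = DEFAULT_ALPHA
    q: float | None = DEFAULT_FDR_Q
    group: str | None = None
    m_g: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency size does not match gene_ids")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu] == 1
        return [
            (self.gene_ids[i], self.gene_ids[j])
            for i, j in zip(iu[0][mask], iu[1][mask])
        ]


@dataclass
class CorrelationTestResult:
    """Pairwise Spearman coefficients with asymptotic and BH-adjusted p-values.

    Matrices are symmetric; the diagonal is not a tested pair (rho fixed at
    1, p and q at 0) and is excluded from the BH family.
    """

    rho: np.ndarray
    p: np.ndarray
    m_g: int
    q_bh: np.ndarray | None = None


def spearman_matrix(values: np.ndarray, gene_ids: Sequence[str] | None = None) -> np.ndarray:
    """All-pairs Spearman correlation of gene rows (mid-ranks, then Pearson).

    ``values`` is genes x samples for one phenotype group. Constant rows have
    no defined rank correlation and raise, naming the gene.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-d genes x samples array")
    n, m = x.shape
    if m < 3:
        raise ValueError("need at least 3 samples per group")
    const = np.ptp(x, axis=1) == 0
    if const.any():
        i = int(np.flatnonzero(const)[0])
        name = gene_ids[i] if gene_ids is not None else f"row {i}"
        raise ValueError(f"constant expression for gene {name}: correlation undefined")
    ranks = sps.rankdata(x, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    rho = (centered @ centered.T) / np.outer(norms, norms)
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def correlation_pvalues(rho: np.ndarray, m_g: int) -> np.ndarray:
    """Two-sided asymptotic no-correlation p-values for a rho matrix.

    ``p = 2 * (1 - Phi(|rho| * sqrt(m_g - 1)))``; the diagonal is set to 0
    as a placeholder (it is never part of the tested family).
    """
    if m_g < MIN_GROUP_SIZE:
        raise ValueError(
            f"asymptotic test requires at least {MIN_GROUP_SIZE} samples, got {m_g}"
        )
    z = np.abs(rho) * np.sqrt(m_g - 1)
    p = 2.0 * sps.norm.sf(z)
    np.clip(p, 0.0, 1.0, out=p)
    np.fill_diagonal(p, 0.0)
    return p


def call_edges(
    test: CorrelationTestResult,
    alpha: float = DEFAULT_ALPHA,
    q: float = DEFAULT_FDR_Q,
    gene_ids: Sequence[str] | None = None,
    group: str | None = None,
) -> CoexpressionNetwork:
    """Threshold pairwise tests into a binary network.

    BH adjustment is computed jointly over the n(n-1)/2 upper-triangle
    p-values (one family per network); an edge requires both ``p < alpha``
    and adjusted value ``< q``. Fills ``test.q_bh``.
    """
    p = test.p
    n = p.shape[0]
    iu = np.triu_indices(n, k=1)
    q_flat = bh_fdr(p[iu])
    q_mat = np.zeros_like(p)
    q_mat[iu] = q_flat
    q_mat += q_mat.T
    test.q_bh = q_mat
    adj = np.zeros((n, n), dtype=np.int8)
    hit = (p[iu] < alpha) & (q_flat < q)
    adj[iu[0][hit], iu[1][hit]] = 1
    adj += adj.T
    ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n)]
    return CoexpressionNetwork(adj, ids, alpha, q, group, test.m_g)


def infer_network(
    dataset: ExpressionDataset,
    group: str,
    alpha: float = DEFAULT_ALPHA,
    q: float = DEFAULT_FDR_Q,
    min_group_size: int = MIN_GROUP_SIZE,
) -> CoexpressionNetwork:
    """Infer one phenotype's co-expression network from a dataset.

    ``min_group_size`` guards the large-sample approximation; lowering it
    below 11 is only sensible for exhaustive toy analyses.
    """
    x = dataset.group_matrix(group)
    m_g = x.shape[1]
    if m_g < min_group_size:
        raise ValueError(
            f"group {group!r} has {m_g} samples, below the minimum {min_group_size}"
        )
    rho = spearman_matrix(x, dataset.gene_ids)
    # p-values computed inline rather than via correlation_pvalues: its
    # sample-size guard must not re-fire when min_group_size was lowered
    z = np.abs(rho) * np.sqrt(m_g - 1)
    p = 2.0 * sps.norm.sf(z)
    np.clip(p, 0.0, 1.0, out=p)
    np.fill_diagonal(p, 0.0)
    test = CorrelationTestResult(rho=rho, p=p, m_g=m_g)
    return call_edges(test, alpha, q, dataset.gene_ids, group)
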