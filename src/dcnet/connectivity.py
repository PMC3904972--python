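"""Gene degrees, differential connectivity and degree-distribution tests.

The degree ``k_i`` of a gene is its number of co-expression edges. The
differential connectivity of gene ``i`` is ``delta_k_i = k_normal - k_cancer``
(positive = loss of connectivity in disease), decomposable exactly into
edges lost minus edges gained. Significance comes from a phenotype-label
permutation test: labels are reshuffled preserving group sizes, BOTH
networks are re-inferred from scratch (including the per-permutation BH
edge calling), and the p-value is the fraction of permutations with
``|delta_k| >= |observed delta_k|`` — a raw proportion, so zero p-values
are possible and reported as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset
from .network import (
    DEFAULT_ALPHA,
    DEFAULT_FDR_Q,
    MIN_GROUP_SIZE,
    CoexpressionNetwork,
    infer_network,
)
from .stats import TailedTestResult, bh_fdr, ks_two_sample, spearman_test

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialConnectivityResult",
    "RandomGraphSpec",
    "degrees",
    "edge_changes",
    "dc_permutation_test",
    "er_random_graph",
    "compare_degree_distributions",
    "interplay_correlations",
    "InterplayEntry",
]


@dataclass
class DifferentialConnectivityResult:
    """Per-gene connectivity changes between the two phenotype networks."""

    gene_ids: list[str]
    k_normal: np.ndarray
    k_cancer: np.ndarray
    delta_k: np.ndarray
    lost: np.ndarray
    gained: np.ndarray
    p_dc: np.ndarray | None = None
    fdr_dc: np.ndarray | None = None
    n_perm: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class RandomGraphSpec:
    """Erdos-Renyi G(n, p) null matched to a real network's average degree."""

    n_nodes: int
    k_mean: float
    seed: int = 0

    @property
    def p_conn(self) -> float:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        p = self.k_mean / (self.n_nodes - 1)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"connection probability {p} outside [0, 1]")
        return p


def degrees(network: CoexpressionNetwork) -> np.ndarray:
    """Per-gene degree ``k_i = sum_j a_ij``."""
    return network.adjacency.sum(axis=1).astype(int)


def edge_changes(
    net_normal: CoexpressionNetwork, net_cancer: CoexpressionNetwork
) -> DifferentialConnectivityResult:
    """Count per-gene lost/gained edges and the degree difference.

    Lost = present in normal only, gained = present in cancer only;
    ``delta_k = lost - gained`` holds identically.
    """
    if net_normal.gene_ids != net_cancer.gene_ids:
        raise ValueError("networks are over different gene universes")
    a_n = net_normal.adjacency
    a_c = net_cancer.adjacency
    lost = ((a_n == 1) & (a_c == 0)).sum(axis=1).astype(int)
    gained = ((a_n == 0) & (a_c == 1)).sum(axis=1).astype(int)
    k_n = degrees(net_normal)
    k_c = degrees(net_cancer)
    return DifferentialConnectivityResult(
        gene_ids=list(net_normal.gene_ids),
        k_normal=k_n,
        k_cancer=k_c,
        delta_k=k_n - k_c,
        lost=lost,
        gained=gained,
    )


def dc_permutation_test(
    dataset: ExpressionDataset,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    q: float = DEFAULT_FDR_Q,
    min_group_size: int = MIN_GROUP_SIZE,
) -> DifferentialConnectivityResult:
    """Permutation test of per-gene differential connectivity.

    Group sizes are preserved under relabelling, keeping the per-group
    asymptotic correlation test comparable across permutations. BH is
    applied across genes for the FDR column.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    ref, cond = dataset.levels

    def infer_pair(pheno: pd.Series) -> tuple[CoexpressionNetwork, CoexpressionNetwork]:
        ds = dataset.with_phenotype(pheno)
        net_ref = infer_network(ds, ref, alpha, q, min_group_size)
        net_cond = infer_network(ds, cond, alpha, q, min_group_size)
        return net_ref, net_cond

    net_n, net_c = infer_pair(dataset.phenotype)
    obs = edge_changes(net_n, net_c)
    abs_obs = np.abs(obs.delta_k)

    rng = np.random.default_rng(seed)
    labels = dataset.phenotype.to_numpy()
    index = dataset.phenotype.index
    exceed = np.zeros(dataset.n_genes, dtype=int)
    for _ in range(n_perm):
        shuffled = pd.Series(rng.permutation(labels), index=index, name="phenotype")
        net_ref_b, net_cond_b = infer_pair(shuffled)
        delta_b = degrees(net_ref_b) - degrees(net_cond_b)
        exceed += np.abs(delta_b) >= abs_obs
    p_dc = exceed / n_perm
    obs.p_dc = p_dc
    obs.fdr_dc = bh_fdr(p_dc)
    obs.n_perm = n_perm
    obs.seed = seed
    return obs


def er_random_graph(spec: RandomGraphSpec) -> CoexpressionNetwork:
    """Erdos-Renyi graph with each pair connected with probability
    ``k_mean / (n - 1)``, independently."""
    p = spec.p_conn
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    adj = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    adj[iu] = rng.random(iu[0].size) < p
    adj += adj.T
    ids = [f"node{i + 1:04d}" for i in range(n)]
    return CoexpressionNetwork(adj, ids, alpha=None, q=None, group="random", m_g=None)


def compare_degree_distributions(
    k_a: Sequence[int], k_b: Sequence[int], alternative: str = "two-sided"
) -> TailedTestResult:
    """Two-sample KS comparison of degree vectors.

    ``alternative="greater"`` tests that ``k_a`` is stochastically greater
    than ``k_b`` — the loss-of-connectivity alternative when ``k_a`` is the
    normal network and ``k_b`` the cancer one. Random-graph deviation checks
    use the two-sided form.
    """
    return ks_two_sample(k_a, k_b, alternative)


@dataclass(frozen=True)
class InterplayEntry:
    """One DC/DE interplay correlation, or the reason it is undefined."""

    name: str
    rho: float | None
    p: float | None
    tail: str | None
    note: str = ""


def interplay_correlations(
    dc: DifferentialConnectivityResult, de_table
) -> dict[str, object]:
    """Correlations linking connectivity changes with DE/DC significance.

    Reports Spearman associations between (i) the DC p-value and the number
    of lost connections (left tail: smaller p should mean more losses),
    (ii) the DE p-value and the number of gained connections (tail chosen by
    the observed sign), and (iii) the DE and DC p-values (two-sided), plus
    the per-gene degree ratio ``(k_cancer + 1) / (k_normal + 1)`` used for
    degree-change summaries (+1 guards zero-degree genes).
    """
    if list(dc.gene_ids) != list(de_table.gene_ids):
        raise ValueError("DC result and DE table are over different gene universes")
    if dc.p_dc is None:
        raise ValueError("DC result lacks permutation p-values")

    entries: list[InterplayEntry] = []

    def attempt(name: str, x: np.ndarray, y: np.ndarray, tail: str) -> None:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            entries.append(
                InterplayEntry(name, None, None, None, "constant input, correlation undefined")
            )
            return
        res = spearman_test(x, y, tail)
        entries.append(InterplayEntry(name, res.statistic, res.p, res.tail))

    attempt("p_dc_vs_lost", dc.p_dc, dc.lost.astype(float), "less")

    gained = dc.gained.astype(float)
    p_de = np.asarray(de_table.p_de, dtype=float)
    if np.ptp(gained) == 0 or np.ptp(p_de) == 0:
        entries.append(
            InterplayEntry("p_de_vs_gained", None, None, None, "constant input, correlation undefined")
        )
    else:
        sign = spearman_test(p_de, gained, "two-sided").statistic
        tail = "greater" if sign >= 0 else "less"
        res = spearman_test(p_de, gained, tail)
        entries.append(InterplayEntry("p_de_vs_gained", res.statistic, res.p, res.tail))

    attempt("p_de_vs_p_dc", p_de, np.asarray(dc.p_dc, dtype=float), "two-sided")

    degree_ratio = (dc.k_cancer + 1) / (dc.k_normal + 1)
    return {"correlations": entries, "degree_ratio": degree_ratio}
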