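"""Gene-set enrichment for differential expression and connectivity.

Two complementary set-level analyses:

* **Random-set DE enrichment** — a gene set's mean quantile score is
  restandardized against the exact mean and standard error of the mean of a
  same-size set drawn without replacement from the full score list,
  ``Z = (mean_S - mu) / (sigma * sqrt((G - m) / (m (G - 1))))``. This makes
  Z exactly mean-0 / variance-1 over all same-size subsets, so significance
  is judged against both nulls at once: no phenotype association (tested by
  sample-label permutation, restandardization recomputed inside each
  permutation) and no dependence on which genes form the set.
* **DEC enrichment** — each gene gets ``u = max(-log10 p_DE, -log10 p_DC)``
  after flooring the p-values, i.e. a gene scores high when it is
  differentially expressed OR differentially connected; a set's score is
  the mean ``u`` of its members, judged against same-size random gene sets.

A curated "core set" of disease pathways is used to benchmark the two
metrics: each metric's weighted count of recovered core pathways,
``S = sum_j max(0, 1 - p_j / alpha)``, is compared and the difference is
referred to random pathway subsets of the same size.

Empirical p-values are raw exceedance proportions (zero allowed), matching
the permutation convention used for gene-level differential connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GeneScoreTable, de_score, pooled_ttest
from .io import ExpressionDataset, GeneSetCollection
from .stats import bh_fdr, fisher_combined

__all__ = [
    "EnrichmentTable",
    "CoreSetComparison",
    "restandardized_score",
    "rs_de_enrichment",
    "dec_statistic",
    "dec_enrichment",
    "meta_combine",
    "core_set_score",
    "core_set_comparison",
    "ranked_core_recovery",
]

DEFAULT_CORE_ALPHA = 0.01


@dataclass
class EnrichmentTable:
    """Per-set enrichment scores with empirical p-values and BH-FDR."""

    names: list[str]
    sizes: np.ndarray
    score: np.ndarray
    p_emp: np.ndarray
    fdr: np.ndarray
    n_resamples: int
    mode: str  # "de" (restandardized Z) or "dec" (mean u)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "size": self.sizes,
                "score": self.score,
                "p_emp": self.p_emp,
                "fdr": self.fdr,
            }
        )

    def p_by_name(self) -> dict[str, float]:
        return dict(zip(self.names, self.p_emp))


@dataclass(frozen=True)
class CoreSetComparison:
    """Weighted core-set recovery of the DEC metric versus the DE metric."""

    s_de: float
    s_dec: float
    d: float
    p_perm: float
    n_draws: int
    core_size: int
    seed: int | None = None


def restandardized_score(scores: np.ndarray, member_idx: Sequence[int]) -> float:
    """Standardize a set's mean score against the random-set null.

    With ``G`` genes, a size-``m`` set drawn without replacement has mean
    ``mu`` and standard error ``sigma * sqrt((G - m) / (m (G - 1)))`` where
    ``mu``/``sigma`` are the mean and (population) standard deviation of the
    full score list; Z is the set mean on that scale.
    """
    scores = np.asarray(scores, dtype=float)
    idx = np.asarray(member_idx, dtype=int)
    g = scores.size
    m = idx.size
    if not (1 <= m < g):
        raise ValueError(f"set size {m} must satisfy 1 <= m < universe size {g}")
    mu = scores.mean()
    sigma = scores.std(ddof=0)
    if sigma == 0:
        raise ValueError("all gene scores identical: restandardization undefined")
    se = sigma * np.sqrt((g - m) / (m * (g - 1)))
    return float((scores[idx].mean() - mu) / se)


def _member_indices(
    sets: GeneSetCollection, gene_ids: Sequence[str]
) -> dict[str, np.ndarray]:
    pos = {g: i for i, g in enumerate(gene_ids)}
    return {
        name: np.array([pos[g] for g in members], dtype=int)
        for name, members in sets.items()
    }


def rs_de_enrichment(
    dataset: ExpressionDataset,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 2,
) -> EnrichmentTable:
    """Random-set DE enrichment with a sample-label permutation null.

    For each of ``n_perm`` label shuffles (group sizes preserved) the t
    statistics, quantile scores and restandardized Z are recomputed from
    scratch; ``p_emp`` is the fraction of permutations with
    ``Z_perm >= Z_observed``, BH-adjusted across sets.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    sets = sets.restrict(dataset.gene_ids, min_size=min_size)
    if len(sets) == 0:
        raise ValueError("no gene sets survive restriction to the dataset universe")
    idx_by_set = _member_indices(sets, dataset.gene_ids)

    _, cond = dataset.levels
    x = dataset.values.to_numpy(float)
    is_cond = (dataset.phenotype == cond).to_numpy()

    def z_scores(mask: np.ndarray) -> np.ndarray:
        t, _, df = pooled_ttest(x[:, ~mask], x[:, mask])
        s = de_score(t, df)
        return np.array([restandardized_score(s, idx_by_set[n]) for n in sets.names])

    z_obs = z_scores(is_cond)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(sets), dtype=int)
    for _ in range(n_perm):
        exceed += z_scores(rng.permutation(is_cond)) >= z_obs
    p_emp = exceed / n_perm
    sizes = np.array([idx_by_set[n].size for n in sets.names])
    return EnrichmentTable(
        names=sets.names,
        sizes=sizes,
        score=z_obs,
        p_emp=p_emp,
        fdr=bh_fdr(p_emp),
        n_resamples=n_perm,
        mode="de",
        seed=seed,
    )


def dec_statistic(
    p_de: np.ndarray, p_dc: np.ndarray, floor: float
) -> np.ndarray:
    """Per-gene combined DE-or-DC statistic.

    ``u = max(-log10 max(p_DE, floor), -log10 max(p_DC, floor))`` — large
    when either p-value is small. ``floor`` (typically 1/B of the DC
    permutation run) caps the contribution of p-values reported as zero.
    """
    p_de = np.asarray(p_de, dtype=float)
    p_dc = np.asarray(p_dc, dtype=float)
    if p_de.shape != p_dc.shape:
        raise ValueError("p_de and p_dc must be aligned")
    if floor <= 0:
        raise ValueError("floor must be positive")
    if np.any(p_de < 0) or np.any(p_dc < 0):
        raise ValueError("p-values must be non-negative")
    u = np.maximum(
        -np.log10(np.maximum(p_de, floor)), -np.log10(np.maximum(p_dc, floor))
    )
    return np.maximum(u, 0.0)


def dec_enrichment(
    u: np.ndarray,
    gene_ids: Sequence[str],
    sets: GeneSetCollection,
    n_draws: int = 1000,
    seed: int | None = None,
    min_size: int = 2,
) -> EnrichmentTable:
    """Gene-set resampling enrichment of the combined DEC statistic.

    A set's score is the mean ``u`` of its members; the null draws
    ``n_draws`` same-size gene sets uniformly without replacement from the
    universe, and ``p_emp`` is the fraction of draws whose mean is at least
    the observed one, BH-adjusted across sets.
    """
    u = np.asarray(u, dtype=float)
    if u.size != len(gene_ids):
        raise ValueError("u and gene_ids must be aligned")
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    sets = sets.restrict(gene_ids, min_size=min_size)
    if len(sets) == 0:
        raise ValueError("no gene sets survive restriction to the dataset universe")
    idx_by_set = _member_indices(sets, gene_ids)

    rng = np.random.default_rng(seed)
    names = sets.names
    obs = np.array([u[idx_by_set[n]].mean() for n in names])
    sizes = np.array([idx_by_set[n].size for n in names])

    p_emp = np.empty(len(names))
    null_by_size: dict[int, np.ndarray] = {}
    for size in np.unique(sizes):
        draws = np.empty(n_draws)
        for b in range(n_draws):
            draws[b] = u[rng.choice(u.size, size=size, replace=False)].mean()
        null_by_size[int(size)] = draws
    for j, (m, o) in enumerate(zip(sizes, obs)):
        p_emp[j] = float(np.mean(null_by_size[int(m)] >= o))
    return EnrichmentTable(
        names=names,
        sizes=sizes,
        score=obs,
        p_emp=p_emp,
        fdr=bh_fdr(p_emp),
        n_resamples=n_draws,
        mode="dec",
        seed=seed,
    )


def meta_combine(tables: Sequence[EnrichmentTable]) -> dict[str, float]:
    """Fisher-combine each set's empirical p-values across tissues/studies.

    Sets must be shared across tables; each table's p-values are floored at
    ``1 / n_resamples`` before the log transform.
    """
    if len(tables) == 0:
        raise ValueError("need at least one enrichment table")
    names = set(tables[0].names)
    for t in tables[1:]:
        names &= set(t.names)
    if not names:
        raise ValueError("no gene sets shared across tables")
    combined: dict[str, float] = {}
    for name in tables[0].names:
        if name not in names:
            continue
        ps = []
        for t in tables:
            p = t.p_by_name()[name]
            ps.append(max(p, 1.0 / t.n_resamples))
        combined[name] = fisher_combined(ps)
    return combined


def core_set_score(
    p_by_pathway: Mapping[str, float],
    core: Sequence[str],
    alpha: float = DEFAULT_CORE_ALPHA,
) -> float:
    """Weighted count of recovered core pathways at level ``alpha``.

    Each core pathway contributes ``max(0, 1 - p / alpha)``: weight 1 at
    p = 0, linearly down to 0 at and above ``alpha`` — a smoothed version of
    counting core pathways significant at ``alpha``.
    """
    unknown = [c for c in core if c not in p_by_pathway]
    if unknown:
        raise ValueError(f"core pathways not in the scored collection: {unknown[:5]}")
    return float(sum(max(0.0, 1.0 - p_by_pathway[c] / alpha) for c in core))


def core_set_comparison(
    de_table: EnrichmentTable,
    dec_table: EnrichmentTable,
    core: Sequence[str],
    n_draws: int = 10000,
    seed: int | None = None,
    alpha: float = DEFAULT_CORE_ALPHA,
) -> CoreSetComparison:
    """Test whether DEC recovers the core set better than DE alone.

    ``D = S_DEC(core) - S_DE(core)`` is referred to the distribution of the
    same difference over ``n_draws`` random pathway subsets of size
    ``|core|`` drawn from the whole collection; ``p_perm`` is the fraction
    of draws with ``D_random >= D``.
    """
    if set(de_table.names) != set(dec_table.names):
        raise ValueError("DE and DEC tables cover different pathway collections")
    names = list(de_table.names)
    core = list(core)
    if len(core) > len(names):
        raise ValueError("core set larger than the pathway collection")
    p_de = de_table.p_by_name()
    p_dec = dec_table.p_by_name()
    s_de = core_set_score(p_de, core, alpha)
    s_dec = core_set_score(p_dec, core, alpha)
    d_obs = s_dec - s_de

    rng = np.random.default_rng(seed)
    exceed = 0
    k = len(core)
    for _ in range(n_draws):
        draw = [names[i] for i in rng.choice(len(names), size=k, replace=False)]
        d_r = core_set_score(p_dec, draw, alpha) - core_set_score(p_de, draw, alpha)
        exceed += d_r >= d_obs
    return CoreSetComparison(
        s_de=s_de,
        s_dec=s_dec,
        d=d_obs,
        p_perm=exceed / n_draws,
        n_draws=n_draws,
        core_size=k,
        seed=seed,
    )


def ranked_core_recovery(
    table: EnrichmentTable, core: Sequence[str], top: int
) -> int:
    """Number of core pathways among the first ``top`` ranked positions.

    Pathways are ranked by ascending empirical p with ties broken by name
    for determinism.
    """
    order = sorted(zip(table.p_emp, table.names))
    top_names = {name for _, name in order[:top]}
    return sum(1 for c in core if c in top_names)
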