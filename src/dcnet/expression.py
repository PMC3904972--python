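"""Two-sample differential expression and the normal-quantile gene score.

DE uses the classic pooled-variance Student t-test (two-tailed, with
``m1 + m2 - 2`` degrees of freedom) with BH correction across genes. The
per-gene score feeding set enrichment is the normal-quantile transform of
the t statistic, ``s = |Phi^{-1}(F_df(t))|``: mapping t through its own CDF
and back through the standard normal quantile yields an N(0,1)-scale score
under the null, and folding by absolute value lets up- and down-regulated
genes contribute alike to a pathway's enrichment (a signed variant is
available for direction-aware analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

from .io import ExpressionDataset
from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["GeneScoreTable", "ttest_de", "de_score", "pooled_ttest"]


@dataclass
class GeneScoreTable:
    """Per-gene DE statistics and derived scores.

    ``u`` (the combined DE-or-DC statistic) is filled by the enrichment
    stage; it is ``None`` until then.
    """

    gene_ids: list[str]
    t: np.ndarray
    p_de: np.ndarray
    fdr_de: np.ndarray
    s: np.ndarray
    df: int
    u: np.ndarray | None = None


def pooled_ttest(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Row-wise pooled-variance two-sample t-test.

    ``x1``/``x2`` are genes x samples for the two groups; returns
    ``(t, two-tailed p, df)`` with ``t`` in the direction ``x2 - x1``
    (condition minus reference, so positive t = higher in the second group).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    m1, m2 = x1.shape[1], x2.shape[1]
    if m1 < 2 or m2 < 2:
        raise ValueError("each group needs at least 2 samples")
    df = m1 + m2 - 2
    var1 = x1.var(axis=1, ddof=1)
    var2 = x2.var(axis=1, ddof=1)
    s2p = ((m1 - 1) * var1 + (m2 - 1) * var2) / df
    denom = np.sqrt(s2p * (1.0 / m1 + 1.0 / m2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x2.mean(axis=1) - x1.mean(axis=1)) / denom
    p = 2.0 * sps.t.sf(np.abs(t), df)
    np.clip(p, 0.0, 1.0, out=p)
    return t, p, df


def ttest_de(dataset: ExpressionDataset, signed_score: bool = False) -> GeneScoreTable:
    """Per-gene DE table: t, two-tailed p, BH-FDR and the quantile score.

    Genes with zero pooled variance (flat in both groups) cannot be tested;
    they are excluded from the table with a logged count. Datasets built
    through :meth:`ExpressionDataset.from_parts` have already dropped them.
    """
    ref, cond = dataset.levels
    x_ref = dataset.group_matrix(ref)
    x_cond = dataset.group_matrix(cond)
    t, p, df = pooled_ttest(x_ref, x_cond)
    ok = np.isfinite(t)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("excluded %d genes with zero pooled variance from DE", n_bad)
    gene_ids = [g for g, keep in zip(dataset.gene_ids, ok) if keep]
    t, p = t[ok], p[ok]
    return GeneScoreTable(
        gene_ids=gene_ids,
        t=t,
        p_de=p,
        fdr_de=bh_fdr(p),
        s=de_score(t, df, signed=signed_score),
        df=df,
    )


def de_score(t: np.ndarray | float, df: int, signed: bool = False) -> np.ndarray:
    """Normal-quantile transform of a t statistic.

    ``s = |Phi^{-1}(F_df(t))|`` computed through the upper tail for
    numerical stability at large ``|t|`` (``F`` is the Student-t CDF with
    ``df`` degrees of freedom, ``Phi`` the standard normal CDF). With
    ``signed=True`` the sign of ``t`` is restored.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t statistics must be finite")
    tail = sps.t.sf(np.abs(t_arr), df)  # upper-tail mass, <= 1/2
    # Phi^{-1}(1 - tail) via the complementary quantile keeps precision
    s = -special.ndtri(np.minimum(tail, 0.5))
    s = np.maximum(s, 0.0)
    if signed:
        s = np.sign(t_arr) * s
    return s if np.ndim(t) else float(s)
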