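"""Shared statistical primitives.

Small, heavily-tested wrappers used by every analysis stage: Benjamini-
Hochberg step-up adjustment, the two-sample Kolmogorov-Smirnov test, the
hypergeometric over-representation ("Fisher exact") tail, Fisher's combined
probability statistic, and the large-sample Spearman rank-correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

Tail = Literal["two-sided", "less", "greater"]

__all__ = [
    "TailedTestResult",
    "bh_fdr",
    "ks_two_sample",
    "fisher_exact_enrichment",
    "fisher_combined",
    "spearman_test",
]


@dataclass(frozen=True)
class TailedTestResult:
    """A test statistic with its p-value and the tail that produced it."""

    statistic: float
    p: float
    tail: Tail

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    Adjusted values are ``min_{j >= i} p_(j) * m / j`` on the sorted list,
    capped at 1, then mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], alternative: Tail = "two-sided"
) -> TailedTestResult:
    """Two-sample Kolmogorov-Smirnov test with asymptotic p-value.

    ``alternative="greater"`` tests the alternative that ``x`` is
    stochastically greater than ``y`` (its ECDF lies below); ``"less"`` the
    reverse; ``"two-sided"`` uses the absolute ECDF gap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    # scipy's 'less'/'greater' refer to the ECDF of x, so stochastic
    # ordering of the values maps to the opposite keyword.
    scipy_alt = {"two-sided": "two-sided", "greater": "less", "less": "greater"}[
        alternative
    ]
    res = sps.ks_2samp(x, y, alternative=scipy_alt, method="asymp")
    return TailedTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), alternative)


def fisher_exact_enrichment(
    universe: int, set_a: int, set_b: int, overlap: int
) -> TailedTestResult:
    """One-sided over-representation p-value for the overlap of two gene lists.

    ``P(X >= overlap)`` with ``X ~ Hypergeometric(universe, set_a, set_b)``:
    the chance that two lists of the given sizes, drawn at random from the
    universe, share at least ``overlap`` genes.
    """
    if not (0 <= set_a <= universe and 0 <= set_b <= universe):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= overlap <= min(set_a, set_b)):
        raise ValueError("overlap inconsistent with set sizes")
    if overlap < max(0, set_a + set_b - universe):
        raise ValueError("overlap smaller than forced minimum")
    p = float(sps.hypergeom.sf(overlap - 1, universe, set_a, set_b))
    return TailedTestResult(float(overlap), min(p, 1.0), "greater")


def fisher_combined(p_values: Sequence[float]) -> float:
    """Fisher's combined probability of independent p-values.

    ``X2 = -2 * sum(log p_i)`` referred to a chi-square distribution with
    ``2k`` degrees of freedom. Zeros are a contract violation: callers floor
    permutation p-values (at 1/B) before combining.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]; floor zeros upstream")
    x2 = -2.0 * float(np.log(p).sum())
    return float(sps.chi2.sf(x2, 2 * p.size))


def spearman_test(
    x: Sequence[float], y: Sequence[float], tail: Tail = "two-sided"
) -> TailedTestResult:
    """Spearman rank correlation with a large-sample normal p-value.

    Mid-ranks are assigned to ties and rho is the Pearson correlation of the
    ranks; under no association ``z = rho * sqrt(n - 1)`` is asymptotically
    standard normal. ``tail="greater"`` tests for positive association.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    z = rho * np.sqrt(n - 1)
    if tail == "two-sided":
        p = 2.0 * float(sps.norm.sf(abs(z)))
    elif tail == "greater":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return TailedTestResult(rho, min(p, 1.0), tail)
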