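"""Synthetic two-condition expression data with planted structure.

The generator emulates the qualitative structure of paired normal/cancer
co-expression studies: correlated gene modules in the reference condition, a
planted subset of module genes whose correlations vanish in the disease
condition (loss of connectivity), and a planted subset of mean-shifted
(differentially expressed) genes.

Each module is driven by a Gaussian latent factor: in the normal condition a
module gene reads ``x = sqrt(rho) * f_b + sqrt(1 - rho) * eps`` with factor
``f_b`` and noise ``eps`` independent standard normal per sample, so every
within-module gene pair has Pearson correlation ``rho`` and unit marginal
variance. Background genes are pure noise. In the cancer condition planted
DC genes are detached from their factor (pure noise, still unit variance),
and planted DE genes gain ``effect_size`` standard deviations of mean shift.
The latent-factor construction guarantees a positive-definite covariance at
any size, which an explicit covariance matrix would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "generate_null_pair"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults follow the desk-scale planted design used throughout the test
    suite: 200 genes in two 40-gene modules, within-module correlation 0.7,
    30 samples per phenotype (inside the 14-58 per-group range of typical
    two-condition microarray cohorts), a quarter of module genes detached in
    cancer and a 10% DE prevalence at one standard deviation of shift.
    """

    n_genes: int = 200
    samples_per_group: int = 30
    n_blocks: int = 2
    block_size: int = 40
    rho: float = 0.7
    dc_fraction: float = 0.25
    de_fraction: float = 0.10
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("n_blocks * block_size exceeds n_genes")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        for name in ("dc_fraction", "de_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 1 or self.samples_per_group < 1:
            raise ValueError("n_genes and samples_per_group must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    planted_dc_genes: FrozenSet[str]
    planted_de_genes: FrozenSet[str]
    config: SyntheticConfig = field(repr=False, default=SyntheticConfig())


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw one two-condition dataset with planted DC and DE genes.

    Deterministic given ``config.seed``. DC genes are sampled among module
    genes, DE genes among all genes; the two draws are independent, so their
    overlap is whatever chance produces (the truth records both sets).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.samples_per_group
    genes = _gene_ids(n)

    block_of = np.full(n, -1, dtype=int)  # -1 = background noise gene
    for b in range(config.n_blocks):
        block_of[b * config.block_size : (b + 1) * config.block_size] = b
    block_gene_idx = np.flatnonzero(block_of >= 0)

    n_dc = int(round(config.dc_fraction * block_gene_idx.size))
    dc_idx = rng.choice(block_gene_idx, size=n_dc, replace=False) if n_dc else np.array([], dtype=int)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    detached = np.zeros(n, dtype=bool)
    detached[dc_idx] = True

    w = np.sqrt(config.rho)
    w_noise = np.sqrt(1.0 - config.rho)

    def draw(condition: str) -> np.ndarray:
        factors = rng.standard_normal((max(config.n_blocks, 1), m))
        eps = rng.standard_normal((n, m))
        x = eps.copy()
        in_block = block_of >= 0
        use_factor = in_block if condition == "normal" else (in_block & ~detached)
        rows = np.flatnonzero(use_factor)
        x[rows] = w * factors[block_of[rows]] + w_noise * eps[rows]
        if condition == "cancer" and de_idx.size:
            x[de_idx] += config.effect_size
        return x

    x_normal = draw("normal")
    x_cancer = draw("cancer")

    sample_ids = [f"normal_{i + 1:03d}" for i in range(m)] + [
        f"cancer_{i + 1:03d}" for i in range(m)
    ]
    values = pd.DataFrame(
        np.hstack([x_normal, x_cancer]), index=genes, columns=sample_ids
    )
    phenotype = pd.Series(
        ["normal"] * m + ["cancer"] * m,
        index=pd.Index(sample_ids, name="sample_id"),
        name="phenotype",
    )
    dataset = ExpressionDataset.from_parts(values, phenotype)
    truth = SyntheticTruth(
        planted_dc_genes=frozenset(genes[i] for i in dc_idx),
        planted_de_genes=frozenset(genes[i] for i in de_idx),
        config=config,
    )
    return dataset, truth


def generate_null_pair(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Global-null dataset: same generative model in both conditions.

    With no planted effects the phenotype labels are exchangeable, making
    this the calibration input for every downstream permutation test.
    """
    null_cfg = replace(config, dc_fraction=0.0, de_fraction=0.0)
    return generate_dataset(null_cfg)
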