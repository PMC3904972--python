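"""Shared fixtures: small deterministic datasets and reference oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcnet import SyntheticConfig, generate_dataset, generate_null_pair
from dcnet.io import ExpressionDataset


def reference_bh(p: np.ndarray) -> np.ndarray:
    """Literal textbook BH step-up: sort, adjust p_(i)*m/i, running min
    from the largest rank down, cap at 1, unsort."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


@pytest.fixture(scope="session")
def planted_study():
    """Default planted design: 200 genes, 2 blocks of 40, rho=0.7,
    30+30 samples, a quarter of block genes detached in cancer, no DE."""
    cfg = SyntheticConfig(de_fraction=0.0, seed=20240501)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Global-null study: 100 independent-ish genes, labels exchangeable."""
    cfg = SyntheticConfig(
        n_genes=100, n_blocks=2, block_size=20, rho=0.5, seed=777
    )
    return generate_null_pair(cfg)


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    """4 genes x 24 samples, two groups of 12, fixed RNG."""
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.normal(size=(4, 24)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(24)],
    )
    pheno = pd.Series(
        ["normal"] * 12 + ["cancer"] * 12,
        index=values.columns,
        name="phenotype",
    )
    return ExpressionDataset.from_parts(values, pheno)
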