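"""Reading and writing expression matrices, phenotype tables, gene sets
and the per-gene / per-pathway result tables.

Expression input is a gene-level, log2-scale matrix: tab-delimited text with
a header row of sample identifiers and gene symbols in the first column. The
phenotype table is a two-column TSV mapping every sample to one of exactly
two labels. Gene-set collections use the GMT dialect (one set per line:
name, description, member genes, tab-separated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column order of the per-gene result table
GENE_TABLE_COLUMNS = [
    "gene symbol",
    "p-value DE",
    "FDR DE",
    "t-test statistics DE",
    "p-value DC",
    "FDR DC",
    "loss of connections",
    "gain of connections",
    "degree difference",
]

#: column order of the per-pathway result table
PATHWAY_TABLE_COLUMNS = [
    "pathway name",
    "p-value DE",
    "FDR DE",
    "p-value DEC",
    "FDR DEC",
    "core set",
]

_FLOAT_FMT = "%.17g"  # full round-trip precision for result tables


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionDataset:
    """A genes x samples log2 expression matrix with a two-group phenotype.

    ``values`` is indexed by unique gene symbols (rows) and unique sample
    identifiers (columns); ``phenotype`` maps each sample to one of exactly
    two labels. ``levels`` orders the two labels as (reference, condition) —
    canonically ``("normal", "cancer")`` — and fixes the sign conventions of
    every downstream contrast.
    """

    values: pd.DataFrame
    phenotype: pd.Series
    levels: tuple[str, str]
    n_dropped_missing: int = 0
    n_dropped_constant: int = 0

    @classmethod
    def from_parts(
        cls,
        values: pd.DataFrame,
        phenotype: pd.Series,
        drop_degenerate: bool = True,
    ) -> "ExpressionDataset":
        """Validate and assemble a dataset, dropping unusable gene rows.

        Rows with any missing value are removed, then rows with zero variance
        within either phenotype group (Spearman and t statistics are
        undefined for them); both counts are logged and recorded.
        """
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene symbols: {dupes[:5]}")
        if values.columns.has_duplicates:
            raise DataError("duplicate sample identifiers")
        phenotype = phenotype.reindex(values.columns)
        if phenotype.isna().any():
            missing = list(values.columns[phenotype.isna()])
            raise DataError(f"samples without phenotype label: {missing[:5]}")
        labels = pd.unique(phenotype)
        if len(labels) != 2:
            raise DataError(
                f"phenotype must have exactly 2 groups, found {len(labels)}"
            )
        levels = _order_levels(labels)

        n_missing = 0
        n_constant = 0
        if drop_degenerate:
            keep = values.notna().all(axis=1)
            n_missing = int((~keep).sum())
            values = values.loc[keep]
            const = np.zeros(len(values), dtype=bool)
            for lab in levels:
                sub = values.loc[:, phenotype == lab].to_numpy(float)
                const |= np.ptp(sub, axis=1) == 0
            n_constant = int(const.sum())
            values = values.loc[~const]
            if n_missing:
                logger.info("dropped %d gene rows with missing values", n_missing)
            if n_constant:
                logger.info(
                    "dropped %d gene rows constant within a phenotype group",
                    n_constant,
                )
        elif values.isna().any().any():
            raise DataError("missing values present and drop_degenerate=False")
        return cls(values, phenotype, levels, n_missing, n_constant)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        return {lab: int((self.phenotype == lab).sum()) for lab in self.levels}

    def group_matrix(self, label: str) -> np.ndarray:
        """Genes x samples array restricted to one phenotype group."""
        if label not in self.levels:
            raise DataError(f"unknown phenotype group {label!r}")
        return self.values.loc[:, self.phenotype == label].to_numpy(float)

    def with_phenotype(self, phenotype: pd.Series) -> "ExpressionDataset":
        """Same matrix under relabelled samples (for permutation tests)."""
        return ExpressionDataset(self.values, phenotype, self.levels)


def _order_levels(labels: Sequence[str]) -> tuple[str, str]:
    lset = set(labels)
    if lset == {"normal", "cancer"}:
        return ("normal", "cancer")
    a, b = sorted(lset)
    return (a, b)


@dataclass
class GeneSetCollection:
    """Ordered, uniquely named gene sets (pathways)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def restrict(
        self, universe: Sequence[str], min_size: int = 2
    ) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``.

        Exclusions are logged, mirroring how enrichment tools report sets
        that vanish after mapping to the assayed genes.
        """
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        dropped = []
        for name, members in self.sets.items():
            inside = [g for g in members if g in uni]
            if len(inside) >= min_size:
                kept[name] = inside
            else:
                dropped.append(name)
        if dropped:
            logger.info(
                "excluded %d gene sets smaller than %d after restriction: %s",
                len(dropped),
                min_size,
                ", ".join(dropped[:5]),
            )
        return GeneSetCollection(
            kept, {n: self.descriptions.get(n, "") for n in kept}
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, phenotype_path: str | Path) -> ExpressionDataset:
    """Load an expression matrix and its phenotype table into a dataset.

    Raises :class:`DataError` naming the offending row/column on non-numeric
    cells, unknown samples, or a phenotype with other than two groups.
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip().str.lower() != "nan")
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise DataError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} in {matrix_path}"
            )
        values[col] = converted

    pheno = read_phenotype(phenotype_path)
    unknown = [s for s in pheno.index if s not in values.columns]
    if unknown:
        raise DataError(f"phenotype file lists unknown samples: {unknown[:5]}")
    return ExpressionDataset.from_parts(values, pheno)


def read_phenotype(path: str | Path) -> pd.Series:
    """Two-column TSV ``sample_id<TAB>phenotype`` (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise DataError(f"phenotype file must have 2 columns, found {df.shape[1]}")
    if df.iloc[:, 0].duplicated().any():
        raise DataError("duplicate sample ids in phenotype file")
    return pd.Series(
        df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="sample_id"),
        name="phenotype",
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file, de-duplicating members within each set."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one member"
                )
            name, desc, *members = fields
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in members:
                if g:
                    seen.setdefault(g)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    phenotype_path: str | Path,
) -> None:
    """Write a dataset back to matrix + phenotype TSVs (full precision)."""
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    dataset.values.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
    pheno = dataset.phenotype.rename_axis("sample_id").reset_index()
    pheno.to_csv(phenotype_path, sep="\t", index=False)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def gene_table_frame(
    gene_ids: Sequence[str],
    p_de: np.ndarray,
    fdr_de: np.ndarray,
    t_de: np.ndarray,
    p_dc: np.ndarray,
    fdr_dc: np.ndarray,
    lost: np.ndarray,
    gained: np.ndarray,
    delta_k: np.ndarray,
) -> pd.DataFrame:
    """Assemble the per-gene result table, ranked by descending ``|delta_k|``
    with ties broken by gene symbol."""
    df = pd.DataFrame(
        {
            "gene symbol": list(gene_ids),
            "p-value DE": p_de,
            "FDR DE": fdr_de,
            "t-test statistics DE": t_de,
            "p-value DC": p_dc,
            "FDR DC": fdr_dc,
            "loss of connections": np.asarray(lost, dtype=int),
            "gain of connections": np.asarray(gained, dtype=int),
            "degree difference": np.asarray(delta_k, dtype=int),
        }
    )
    df["_abs"] = df["degree difference"].abs()
    df = df.sort_values(["_abs", "gene symbol"], ascending=[False, True], kind="mergesort")
    return df.drop(columns="_abs").reset_index(drop=True)


def write_gene_table(
    table: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write the per-gene result table as TSV."""
    missing = [c for c in GENE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"gene table missing columns: {missing}")
    _write_tsv(table[GENE_TABLE_COLUMNS], path, header_lines)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_pathway_table(
    table: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write the per-pathway enrichment table (DE and DEC p-values, core flag)."""
    missing = [c for c in PATHWAY_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"pathway table missing columns: {missing}")
    _write_tsv(table[PATHWAY_TABLE_COLUMNS], path, header_lines)


def read_pathway_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_report(
    rows: Sequence[Mapping[str, object]], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a generic long-format report (list of dict rows) as TSV."""
    _write_tsv(pd.DataFrame(list(rows)), path, header_lines)
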