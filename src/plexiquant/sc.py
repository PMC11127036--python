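"""Single-cell expressing fractions and sample x cell-type pseudo-bulk.

Works on a sparse gene x cell raw-count matrix with per-cell metadata
(sample, tissue, cell type, health status), the export shape of a
single-cell portal accession (MTX triplet plus a metadata table).  The two
core quantities are the *expressing fraction* — the percentage of cells of
a subset with a nonzero raw count for one gene — and the *pseudo-bulk*
table obtained by summing raw counts over (sample, cell type) strata.
Differential testing on the pseudo-bulk table is deliberately left to
standard DE tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

ALLOWED_TISSUES = frozenset({"colon", "terminal_ileum"})
ALLOWED_STATUS = frozenset({"healthy", "non_inflamed", "inflamed"})
REQUIRED_METADATA = ("sample_id", "tissue", "cell_type", "status")


@dataclass
class SCMatrix:
    """Sparse non-negative integer gene x cell matrix with cell metadata.

    ``cell_metadata`` is indexed by barcode and must carry the columns
    ``sample_id``, ``tissue``, ``cell_type`` and ``status`` with values
    from the declared vocabularies.
    """

    matrix: sparse.spmatrix
    gene_names: list[str]
    cell_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        if self.matrix.shape[0] != len(self.gene_names):
            raise ValueError(
                f"{len(self.gene_names)} gene names for {self.matrix.shape[0]} rows"
            )
        dupes = pd.Index(self.gene_names)[pd.Index(self.gene_names).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))}")
        if self.matrix.shape[1] != len(self.cell_metadata):
            raise ValueError(
                f"metadata has {len(self.cell_metadata)} rows for "
                f"{self.matrix.shape[1]} cells"
            )
        missing = [c for c in REQUIRED_METADATA if c not in self.cell_metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad_tissue = set(self.cell_metadata["tissue"]) - ALLOWED_TISSUES
        if bad_tissue:
            raise ValueError(f"unknown tissue labels: {sorted(bad_tissue)}")
        bad_status = set(self.cell_metadata["status"]) - ALLOWED_STATUS
        if bad_status:
            raise ValueError(f"unknown status labels: {sorted(bad_status)}")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.matrix.nnz and np.any(self.matrix.data != np.round(self.matrix.data)):
            raise ValueError("counts must be integers")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


def load_sc_dataset(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path,
) -> SCMatrix:
    """Ingest an MTX triplet (matrix, features, barcodes) plus metadata table.

    The metadata table (TSV/CSV, sniffed by extension) must have a
    ``barcode`` column covering every barcode of the triplet; mismatches
    raise an error naming the offending barcodes.
    """
    matrix = sparse.csr_matrix(scio.mmread(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None)
    gene_names = features.iloc[:, 0].astype(str).tolist()
    barcodes = (
        pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    )
    sep = "," if str(metadata_path).endswith(".csv") else "\t"
    metadata = pd.read_csv(metadata_path, sep=sep)
    if "barcode" not in metadata.columns:
        raise ValueError("metadata table needs a 'barcode' column")
    metadata = metadata.set_index("barcode")
    if len(barcodes) != matrix.shape[1]:
        raise ValueError(
            f"{len(barcodes)} barcodes for {matrix.shape[1]} matrix columns"
        )
    missing = [b for b in barcodes if b not in metadata.index]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} barcodes missing from metadata (first: {shown})"
        )
    metadata = metadata.loc[barcodes]
    return SCMatrix(matrix=matrix, gene_names=gene_names, cell_metadata=metadata)


def _subset_mask(
    sc: SCMatrix, subset: Mapping[str, object] | Callable[[pd.DataFrame], pd.Series] | None
) -> np.ndarray:
    meta = sc.cell_metadata
    if subset is None:
        return np.ones(len(meta), dtype=bool)
    if callable(subset):
        return np.asarray(subset(meta), dtype=bool)
    mask = np.ones(len(meta), dtype=bool)
    for column, wanted in subset.items():
        if column not in meta.columns:
            raise KeyError(f"metadata column {column!r} not present")
        if isinstance(wanted, (list, tuple, set, frozenset)):
            mask &= meta[column].isin(list(wanted)).to_numpy()
        else:
            mask &= (meta[column] == wanted).to_numpy()
    return mask


def expressing_fraction(
    sc: SCMatrix,
    gene: str,
    subset: Mapping[str, object] | Callable[[pd.DataFrame], pd.Series] | None = None,
    min_count: int = 1,
) -> float:
    """Percentage of cells in the subset with ``count(gene) >= min_count``.

    ``subset`` is a metadata filter, e.g.
    ``{"tissue": "colon", "status": "healthy", "cell_type": "glia"}``.
    """
    idx = sc.gene_index(gene)
    mask = _subset_mask(sc, subset)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("subset selects no cells")
    row = np.asarray(sc.matrix[idx, :].todense()).ravel()[mask]
    return 100.0 * float(np.count_nonzero(row >= min_count)) / n


@dataclass
class PseudobulkTable:
    """Summed raw counts per (sample, cell type) stratum."""

    counts: pd.DataFrame  # genes x strata
    stratum_metadata: pd.DataFrame  # one row per stratum: keys, status, tissue, n_cells

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())


def aggregate_pseudobulk(
    sc: SCMatrix, by: Sequence[str] = ("sample_id", "cell_type")
) -> PseudobulkTable:
    """Sum raw counts over the strata defined by the ``by`` metadata columns.

    Total count is conserved: the table sums to the matrix total, per gene
    and globally.
    """
    meta = sc.cell_metadata
    for column in by:
        if column not in meta.columns:
            raise KeyError(f"metadata column {column!r} not present")
    keys = meta[list(by)].astype(str).agg("|".join, axis=1)
    strata = pd.unique(keys)
    indicator = sparse.csr_matrix(
        (
            np.ones(len(keys)),
            (np.arange(len(keys)), pd.Categorical(keys, categories=strata).codes),
        ),
        shape=(len(keys), len(strata)),
    )
    summed = np.asarray((sc.matrix @ indicator).todense())
    counts = pd.DataFrame(summed, index=sc.gene_names, columns=list(strata))
    meta_rows = []
    for stratum in strata:
        members = meta[keys == stratum]
        row = {"stratum": stratum, "n_cells": len(members)}
        for column in by:
            row[column] = members[column].iloc[0]
        for column in ("status", "tissue"):
            if column in members.columns and column not in row:
                uniq = members[column].unique()
                row[column] = uniq[0] if len(uniq) == 1 else None
        meta_rows.append(row)
    return PseudobulkTable(
        counts=counts, stratum_metadata=pd.DataFrame(meta_rows).set_index("stratum")
    )


def expression_summary(
    sc: SCMatrix, gene: str, cell_type: str = "glia"
) -> pd.DataFrame:
    """Per (tissue, status) cell counts and expressing percentages for one
    gene within one cell type — the accession-style summary table."""
    rows = []
    meta = sc.cell_metadata
    for tissue in sorted(set(meta["tissue"])):
        for status in sorted(set(meta["status"])):
            subset = {"tissue": tissue, "status": status, "cell_type": cell_type}
            mask = _subset_mask(sc, subset)
            n = int(mask.sum())
            if n == 0:
                continue
            pct = expressing_fraction(sc, gene, subset)
            rows.append(
                {
                    "tissue": tissue,
                    "status": status,
                    "cell_type": cell_type,
                    "n_cells": n,
                    "pct_expressing": pct,
                }
            )
    return pd.DataFrame(rows)
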