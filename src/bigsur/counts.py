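"""UMI count matrices: container, readers, gene filtering, table output.

The internal orientation is genes x cells throughout the package (per-gene
statistics live on rows).  Readers accept the 10x-style Matrix Market
triplet (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, plain or
gzipped) and a dense TSV with genes in rows and a header of cell ids.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneFilterConfig",
    "read_counts",
    "filter_genes",
    "read_gene_list",
    "read_pair_list",
    "write_table",
    "write_counts_mtx",
]


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells.

    ``counts`` is a CSR sparse matrix (rows = genes).  Entries are validated
    to be non-negative integers; gene and cell ids must be unique.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")
        _validate_entries(self.counts)
        self.counts = self.counts.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_means(self) -> np.ndarray:
        return self.gene_totals() / self.n_cells

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[mask], self.gene_ids[mask], self.cell_ids)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[:, mask], self.gene_ids, self.cell_ids[mask])


@dataclass
class GeneFilterConfig:
    """Gene filtering policy.

    ``min_cells_expressed`` is the absolute number of cells in which a gene
    must have at least one UMI to be kept (default 8).  A fraction-of-cells
    alternative may be given instead; if both are set the absolute count
    wins.  ``exclusion_list`` holds gene ids to drop unconditionally
    (e.g. pseudogenes).
    """

    min_cells_expressed: int | None = 8
    min_cells_fraction: float | None = None
    exclusion_list: frozenset = field(default_factory=frozenset)

    def resolve_min_cells(self, n_cells: int) -> int:
        if self.min_cells_expressed is not None:
            k = int(self.min_cells_expressed)
        elif self.min_cells_fraction is not None:
            k = int(np.ceil(self.min_cells_fraction * n_cells))
        else:
            k = 0
        if k < 0 or k > n_cells:
            raise ValidationError(
                f"min_cells_expressed={k} outside [0, n_cells={n_cells}]"
            )
        return k


def _validate_entries(counts: sp.spmatrix) -> None:
    data = counts.tocoo()
    if data.data.size == 0:
        return
    bad = ~np.isfinite(data.data) | (data.data < 0) | (data.data != np.floor(data.data))
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValidationError(
            f"count entry at gene row {data.row[i]}, cell column {data.col[i]} "
            f"is {data.data[i]!r}: entries must be non-negative integers"
        )


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_10x_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / f"{stem}{suffix}"
            if cand.exists():
                return cand
    raise ValidationError(f"none of {list(stems)} found in {directory}")


def read_counts(path: str | Path, format: str = "auto") -> CountMatrix:
    """Read a UMI matrix from disk.

    ``mtx_10x`` expects a directory with matrix.mtx[.gz], features.tsv[.gz]
    (or genes.tsv) and barcodes.tsv[.gz]; genes are rows.  ``dense_tsv``
    expects genes in rows, first column gene ids, header row of cell ids.
    Matrix Market 1-based indices are converted to 0-based internally.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format == "auto":
        format = "mtx_10x" if path.is_dir() else "dense_tsv"

    if format == "mtx_10x":
        mtx = _find_10x_file(path, ["matrix.mtx"])
        feats = _find_10x_file(path, ["features.tsv", "genes.tsv"])
        bcs = _find_10x_file(path, ["barcodes.tsv"])
        with _open_maybe_gzip(mtx) as fh:
            counts = sp.csr_matrix(mmread(fh))
        gene_ids = pd.read_csv(feats, sep="\t", header=None)[0].to_numpy(dtype=object)
        cell_ids = pd.read_csv(bcs, sep="\t", header=None)[0].to_numpy(dtype=object)
        return CountMatrix(counts, gene_ids, cell_ids)

    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        counts = sp.csr_matrix(df.to_numpy())
        return CountMatrix(
            counts,
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )

    raise ValidationError(f"unknown format {format!r}")


def filter_genes(m: CountMatrix, cfg: GeneFilterConfig) -> CountMatrix:
    """Apply the gene filters: exclusion list and minimum-cells-expressed.

    Cells with zero total UMI are dropped first (with a warning) since the
    per-cell expected values downstream are undefined for them.  Gene order
    is preserved; the operation is idempotent.
    """
    cell_tot = m.cell_totals()
    if np.any(cell_tot == 0):
        n_zero = int(np.sum(cell_tot == 0))
        logger.warning("dropping %d cells with zero total UMI", n_zero)
        m = m.subset_cells(cell_tot > 0)

    k = cfg.resolve_min_cells(m.n_cells)
    n_expressed = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    keep = n_expressed >= k
    if cfg.exclusion_list:
        excluded = np.array([g in cfg.exclusion_list for g in m.gene_ids])
        keep &= ~excluded
    if not np.any(keep):
        raise ValidationError("empty matrix after filtering")
    return m.subset_genes(keep)


def read_gene_list(path: str | Path) -> frozenset:
    """One gene id per line; '#' comments and blank lines ignored."""
    out = []
    with _open_maybe_gzip(Path(path)) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line.split("\t")[0])
    return frozenset(out)


def read_pair_list(path: str | Path) -> frozenset:
    """Two tab-separated gene ids per line -> frozenset of frozenset pairs."""
    out = []
    with _open_maybe_gzip(Path(path)) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"pair list line has fewer than 2 fields: {line!r}")
            out.append(frozenset(parts[:2]))
    return frozenset(out)


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a TSV with an optional leading '#' comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_counts_mtx(m: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as a 10x-style Matrix Market triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), m.counts.tocoo())
    pd.Series(m.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(m.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
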