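"""Reading and writing the on-disk conventions: MTX triplets and delimited
tables.

In memory every matrix is cells x features. On disk, Matrix Market files
follow the 10x convention (genes in rows, cells in columns) and are
transposed on read/write; dense delimited files are cells x features with a
header row of feature ids and an index column of cell ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix
from .exceptions import InvalidInputError
from .simulate import SimulatedDataset

__all__ = [
    "read_matrix",
    "read_mtx",
    "read_dense",
    "write_mtx",
    "write_dense",
    "write_simulated",
    "read_simulated",
]


def _read_id_file(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise InvalidInputError(f"missing {what} id file: {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    seen = set()
    for i, name in enumerate(ids):
        if name in seen:
            raise InvalidInputError(f"duplicate id {name!r} at line {i + 1} of {path}")
        seen.add(name)
    return ids


def read_mtx(matrix_path, genes_path, cells_path) -> ExpressionMatrix:
    """Read an MTX triplet (matrix + gene ids + cell ids).

    The matrix file stores genes x cells and is transposed to the in-memory
    cells x genes orientation.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise InvalidInputError(f"missing matrix file: {matrix_path}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as err:
        raise InvalidInputError(f"cannot parse Matrix Market file {matrix_path}: {err}") from err
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = _read_id_file(Path(genes_path), "gene")
    cells = _read_id_file(Path(cells_path), "cell")
    if mat.shape != (len(genes), len(cells)):
        raise InvalidInputError(
            f"matrix {matrix_path} is {mat.shape} but id files give "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return ExpressionMatrix(np.asarray(mat, dtype=float).T, cell_ids=cells, feature_ids=genes)


def read_dense(path, sep: str | None = None) -> ExpressionMatrix:
    """Read a dense delimited cells x features table (header = feature ids,
    first column = cell ids)."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"missing matrix file: {path}")
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[
            [not np.issubdtype(frame[c].dtype, np.number) for c in frame.columns]
        ]
        raise InvalidInputError(f"non-numeric entries in {path}, columns {list(bad)}")
    return ExpressionMatrix(
        values.astype(float),
        cell_ids=list(map(str, frame.index)),
        feature_ids=list(map(str, frame.columns)),
    )


def read_matrix(path, format: str = "auto", genes_path=None, cells_path=None) -> ExpressionMatrix:
    """Dispatch on format: ``mtx`` (triplet with id files) or ``dense``."""
    path = Path(path)
    if format == "auto":
        format = "mtx" if path.suffix == ".mtx" else "dense"
    if format == "mtx":
        if genes_path is None or cells_path is None:
            genes_path = path.with_name("genes.tsv")
            cells_path = path.with_name("barcodes.tsv")
        return read_mtx(path, genes_path, cells_path)
    if format == "dense":
        return read_dense(path)
    raise InvalidInputError(f"unknown matrix format {format!r}")


def write_mtx(X: ExpressionMatrix, matrix_path, genes_path, cells_path) -> None:
    """Write an MTX triplet in the genes x cells on-disk orientation."""
    mat = scipy.sparse.csr_matrix(X.values.T)
    if np.allclose(X.values, np.round(X.values)):
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(str(matrix_path), mat)
    Path(genes_path).write_text("\n".join(X.feature_ids) + "\n")
    Path(cells_path).write_text("\n".join(X.cell_ids) + "\n")


def write_dense(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=sep, index_label="cell_id")


def write_simulated(dataset: SimulatedDataset, outdir) -> dict:
    """Write the simulator outputs: matrix.mtx + genes.tsv + cells.tsv,
    per-cell and per-gene annotation tables, and a JSON config sidecar.
    Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = ExpressionMatrix(
        dataset.counts.astype(float), cell_ids=dataset.cell_ids, feature_ids=dataset.gene_ids
    )
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "cells": outdir / "cells.tsv",
        "gene_annotations": outdir / "gene_annotations.tsv",
        "config": outdir / "config.json",
    }
    write_mtx(X, paths["matrix"], paths["genes"], paths["barcodes"])
    dataset.cells_frame().to_csv(paths["cells"], sep="\t", index=False)
    dataset.genes_frame().to_csv(paths["gene_annotations"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(dataset.config, indent=2) + "\n")
    return paths


def read_simulated(outdir) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Read back a simulator output directory: counts matrix, cell table,
    gene table."""
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t")
    genes = pd.read_csv(outdir / "gene_annotations.tsv", sep="\t")
    mat = scipy.io.mmread(str(outdir / "matrix.mtx"))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    X = ExpressionMatrix(
        np.asarray(mat, dtype=float).T,
        cell_ids=list(cells["cell_id"].astype(str)),
        feature_ids=list(genes["gene_id"].astype(str)),
    )
    return X, cells, genes
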