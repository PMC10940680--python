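"""In-memory containers for expression data and batch/sample design.

The two containers here are deliberately minimal: a cells x features numeric
matrix with string identifiers, and the batch design (which batch each cell
belongs to, plus a numeric label vector per batch, e.g. collection day or
[week, location]). They carry just enough structure for the label-aware
distance model and the preprocessing pipeline; anything richer (AnnData,
SingleCellExperiment) converts trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["ExpressionMatrix", "BatchDesign"]


@dataclass
class ExpressionMatrix:
    """A cells x features real matrix with unique row/column identifiers.

    ``values`` may hold raw counts, log-normalized expression, or principal
    component coordinates — the distance model is agnostic to the space.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default=None)
    feature_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(
                f"expected a 2-D matrix, got shape {self.values.shape}"
            )
        n, k = self.values.shape
        if n < 1 or k < 1:
            raise InvalidInputError("matrix must have at least one cell and one feature")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("matrix contains NaN or infinite values")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"feature{j}" for j in range(k)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.cell_ids) != n:
            raise InvalidInputError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.feature_ids) != k:
            raise InvalidInputError(
                f"{len(self.feature_ids)} feature ids for {k} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise InvalidInputError("cell ids are not unique")
        if len(set(self.feature_ids)) != k:
            raise InvalidInputError("feature ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_ids)


@dataclass
class BatchDesign:
    """Per-cell batch assignment plus a numeric label vector per batch.

    Parameters
    ----------
    batch_of_cell
        Length-n sequence of batch identifiers, one per cell.
    batch_labels
        B x d array (or length-B sequence for scalar labels) of batch-level
        labels such as collection time, aligned with ``batch_ids``. Labels may
        be vectors, e.g. ``[week, location]`` for combined temporal/spatial
        designs.
    batch_ids
        Ordered unique batch identifiers. Defaults to order of first
        appearance in ``batch_of_cell``.
    """

    batch_of_cell: np.ndarray
    batch_labels: np.ndarray
    batch_ids: list = None

    def __post_init__(self) -> None:
        self.batch_of_cell = np.asarray(self.batch_of_cell)
        if self.batch_of_cell.ndim != 1 or len(self.batch_of_cell) < 1:
            raise InvalidInputError("batch_of_cell must be a non-empty 1-D sequence")
        if self.batch_ids is None:
            self.batch_ids = list(pd.unique(self.batch_of_cell))
        else:
            self.batch_ids = list(self.batch_ids)
        if len(set(map(str, self.batch_ids))) != len(self.batch_ids):
            raise InvalidInputError("batch ids are not unique")
        try:
            labels = np.asarray(self.batch_labels, dtype=float)
        except (TypeError, ValueError) as err:
            raise InvalidInputError(
                f"batch labels must be numeric vectors of one dimensionality: {err}"
            ) from err
        if labels.ndim == 1:
            labels = labels[:, None]
        if labels.ndim != 2:
            raise InvalidInputError("batch_labels must be 1-D or 2-D")
        if labels.shape[0] != len(self.batch_ids):
            raise InvalidInputError(
                f"{labels.shape[0]} label vectors for {len(self.batch_ids)} batches"
            )
        if not np.all(np.isfinite(labels)):
            raise InvalidInputError("batch labels contain NaN or infinite values")
        self.batch_labels = labels
        known = set(self.batch_ids)
        missing = {b for b in self.batch_of_cell.tolist() if b not in known}
        if missing:
            raise InvalidInputError(
                f"cells reference batches absent from batch_ids: {sorted(map(str, missing))}"
            )

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)

    @property
    def label_dim(self) -> int:
        return self.batch_labels.shape[1]

    def batch_index_of_cell(self) -> np.ndarray:
        """Integer batch index (into ``batch_ids``) for every cell."""
        lookup = {b: i for i, b in enumerate(self.batch_ids)}
        return np.array([lookup[b] for b in self.batch_of_cell.tolist()], dtype=int)

    @classmethod
    def from_dataframe(
        cls,
        cells: pd.DataFrame,
        batch_col: str,
        label_cols: list[str] | str,
    ) -> "BatchDesign":
        """Build a design from a per-cell annotation table.

        The batch label vector of each batch is taken from that batch's first
        row; all cells of one batch must agree on their label columns.
        """
        if isinstance(label_cols, str):
            label_cols = [label_cols]
        for col in [batch_col, *label_cols]:
            if col not in cells.columns:
                raise InvalidInputError(f"column {col!r} not found in cell annotations")
        batch_ids = list(pd.unique(cells[batch_col]))
        labels = []
        for b in batch_ids:
            sub = cells.loc[cells[batch_col] == b, label_cols]
            if (sub.nunique() > 1).any():
                raise InvalidInputError(
                    f"batch {b!r} has inconsistent values in label columns {label_cols}"
                )
            labels.append(sub.iloc[0].to_numpy(dtype=float))
        return cls(
            batch_of_cell=cells[batch_col].to_numpy(),
            batch_labels=np.asarray(labels, dtype=float),
            batch_ids=batch_ids,
        )
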