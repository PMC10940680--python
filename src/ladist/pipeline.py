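"""End-to-end convenience: counts -> PC embedding -> label-aware embedding.

Wires preprocessing and the distance model together the way the CLI (and the
simulation studies) use them: normalize, log, select HVGs, scale, PCA, fit
the label-aware model with batch = sample and label = day (or any label
columns), and whiten the PC embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BatchDesign, ExpressionMatrix
from .model import LabelAwareDistance, LabelAwareDistanceResults
from .preprocess import PreprocessConfig, preprocess

__all__ = ["LadRun", "run_lad"]


@dataclass
class LadRun:
    """Everything a pipeline run produced."""

    pc_embedding: ExpressionMatrix
    lad_embedding: ExpressionMatrix
    results: LabelAwareDistanceResults
    cells: pd.DataFrame  # annotations of the kept cells
    kept_mask: np.ndarray


def run_lad(
    counts: np.ndarray,
    cells: pd.DataFrame,
    batch_col: str = "batch",
    label_cols: list[str] | str = "day",
    config: PreprocessConfig | None = None,
    length_scale: float = 1.0,
    ridge: float | None = None,
    cell_ids: list[str] | None = None,
) -> LadRun:
    """Run the full chain on a counts matrix plus a per-cell annotation table.

    ``cells`` must carry ``batch_col`` and the numeric ``label_cols`` (one
    column per label dimension, e.g. ``["week", "location"]``).
    """
    embedding, keep = preprocess(counts, config=config, cell_ids=cell_ids)
    cells_kept = cells.loc[keep].reset_index(drop=True)
    design = BatchDesign.from_dataframe(cells_kept, batch_col, label_cols)
    results = LabelAwareDistance(
        embedding, design, length_scale=length_scale, ridge=ridge
    ).fit()
    return LadRun(
        pc_embedding=embedding,
        lad_embedding=results.transform(embedding),
        results=results,
        cells=cells_kept,
        kept_mask=keep,
    )
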