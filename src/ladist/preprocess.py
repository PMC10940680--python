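"""Standard scRNA-seq front-end: normalize, log, HVG, scale, PCA.

Produces the matrix the label-aware distance operates on. Conventions follow
the common Seurat-style protocol: per-cell sum-to-one normalization, a
log(1 + 1e4 * proportion) transform, variance-stabilized highly-variable-gene
ranking, per-gene standardization with sample (n-1) standard deviation, and
PCA with a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "PreprocessConfig",
    "normalize_cells",
    "log_transform",
    "select_hvg",
    "scale_genes",
    "pca",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Pipeline settings; defaults match the common real-data protocol
    (2000 HVGs, 30 PCs); simulation studies use 150 HVGs."""

    n_hvg: int = 2000
    n_pcs: int = 30
    log_transform: bool = True
    log_scale: float = 1e4
    scale_clip: float | None = None


def nonzero_cell_mask(counts: np.ndarray) -> np.ndarray:
    return np.asarray(counts).sum(axis=1) > 0


def normalize_cells(counts: np.ndarray) -> np.ndarray:
    """Scale each cell so its gene expression sums to one.

    All-zero cells are dropped with a warning; an input of only zero cells is
    an error.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InvalidInputError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise InvalidInputError("all cells have zero total expression")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero cells before normalization",
            UserWarning,
            stacklevel=2,
        )
        counts, totals = counts[keep], totals[keep]
    return counts / totals[:, None]


def log_transform(proportions: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log(1 + scale * x) on sum-to-one normalized expression."""
    if not scale > 0:
        raise InvalidParameterError("scale must be > 0")
    return np.log1p(scale * np.asarray(proportions, dtype=float))


def select_hvg(counts: np.ndarray, n_hvg: int) -> np.ndarray:
    """Rank genes by variance standardized against a mean-variance trend.

    The mean-variance trend is a robust local fit: genes are grouped into
    quantile bins of log10(mean), the median log10(variance) per bin forms
    the trend, and each gene's expected variance is interpolated from it. A
    gene's score is its observed variance divided by the trend's prediction,
    so genes more variable than expected at their mean rank first (median
    binning keeps single extreme genes from dragging the trend). Returns the
    indices of the top ``n_hvg`` genes in ascending gene order; ties break by
    gene order. Deterministic.
    """
    counts = np.asarray(counts, dtype=float)
    n_genes = counts.shape[1]
    if not 1 <= n_hvg <= n_genes:
        raise InvalidParameterError(f"n_hvg must be in [1, {n_genes}], got {n_hvg}")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    score = np.full(n_genes, -np.inf)
    ok = (mean > 0) & (var > 0)
    if ok.any():
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        n_bins = max(1, min(20, ok.sum() // 5))
        edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, lm, side="right") - 1, 0, n_bins - 1)
        centers, medians = [], []
        for b in range(n_bins):
            in_bin = which == b
            if in_bin.any():
                centers.append(np.median(lm[in_bin]))
                medians.append(np.median(lv[in_bin]))
        centers, medians = np.asarray(centers), np.asarray(medians)
        order = np.argsort(centers, kind="stable")
        expected = 10.0 ** np.interp(lm, centers[order], medians[order])
        score[ok] = var[ok] / expected
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:n_hvg])


def scale_genes(matrix: np.ndarray, clip: float | None = None) -> np.ndarray:
    """Standardize each gene to mean 0, sample sd (n-1) 1; zero-variance
    genes become all-zero columns. Optionally clip at +/- ``clip``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise InvalidInputError("scaling requires at least 2 cells")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    out = np.zeros_like(matrix)
    nz = sd > 0
    out[:, nz] = (matrix[:, nz] - mean[nz]) / sd[nz]
    if clip is not None:
        if not clip > 0:
            raise InvalidParameterError("scale_clip must be > 0")
        np.clip(out, -clip, clip, out=out)
    return out


def pca(matrix: np.ndarray, n_pcs: int) -> ExpressionMatrix:
    """Scores of the top principal components of the centered matrix.

    Component signs are fixed deterministically: the loading of largest
    magnitude in each component is made positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    max_pcs = min(matrix.shape[0], matrix.shape[1])
    if not 1 <= n_pcs <= max_pcs:
        raise InvalidParameterError(
            f"n_pcs must be in [1, {max_pcs}] for a {matrix.shape} matrix, got {n_pcs}"
        )
    model = PCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(matrix)
    for j in range(n_pcs):
        lead = np.argmax(np.abs(model.components_[j]))
        if model.components_[j, lead] < 0:
            scores[:, j] *= -1.0
    return ExpressionMatrix(scores, feature_ids=[f"PC{j + 1}" for j in range(n_pcs)])


def preprocess(
    counts: np.ndarray,
    config: PreprocessConfig | None = None,
    cell_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Full chain counts -> normalize -> (log) -> HVG -> scale -> PCA.

    HVG ranking is computed on raw counts (vst convention). Zero-variance
    genes within the HVG subset are dropped before PCA. Returns the PC
    embedding and the boolean mask of cells kept (all-zero cells dropped).
    Bit-stable across runs for fixed input and config.
    """
    config = config or PreprocessConfig()
    counts = np.asarray(counts, dtype=float)
    keep = nonzero_cell_mask(counts)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero cells", UserWarning, stacklevel=2
        )
    counts = counts[keep]
    expr = normalize_cells(counts)
    if config.log_transform:
        expr = log_transform(expr, scale=config.log_scale)
    n_hvg = min(config.n_hvg, counts.shape[1])
    hvg = select_hvg(counts, n_hvg)
    expr = expr[:, hvg]
    expr = expr[:, expr.std(axis=0, ddof=1) > 0]
    scaled = scale_genes(expr, clip=config.scale_clip)
    n_pcs = min(config.n_pcs, scaled.shape[0] - 1, scaled.shape[1])
    embedding = pca(scaled, n_pcs)
    if cell_ids is not None:
        kept_ids = [c for c, k in zip(cell_ids, keep) if k]
        embedding = ExpressionMatrix(
            embedding.values, cell_ids=kept_ids, feature_ids=embedding.feature_ids
        )
    return embedding, keep
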