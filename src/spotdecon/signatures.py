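"""Marker-gene ranking and signature-matrix construction from an annotated reference.

The signature matrix ``S`` (signature genes x cell types) holds the mean
expression of each cell type's top marker genes and serves as the design
matrix of the weighted-least-squares deconvolution. Markers are ranked by a
Gini-based one-vs-all score: the Gini coefficient of a gene's across-type mean
expression (specificity) multiplied by a detection-fraction contrast
(fraction of in-type cells expressing the gene minus the fraction of
out-of-type cells expressing it). This is a deliberate, self-contained
definition of a "gini" marker score, not a bit-compatible port of any
particular toolkit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import InputContractError

__all__ = [
    "normalize_library_size",
    "gini_coefficient",
    "rank_markers_gini",
    "build_signature",
    "marker_sets_from_signature",
    "GiniMarkerSelector",
]


def normalize_library_size(expr: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Scale every sample (column) to a common library size.

    Each column is multiplied by ``scale / column_sum`` so that all columns sum
    to ``scale``. All-zero columns are left at zero with a warning.
    """
    if scale <= 0:
        raise InputContractError("scale must be positive")
    sums = expr.sum(axis=0)
    if (sums == 0).all():
        raise InputContractError("all samples have zero total expression")
    if (sums == 0).any():
        warnings.warn(
            f"{int((sums == 0).sum())} sample(s) have zero total counts; left at zero",
            stacklevel=2,
        )
    factors = np.where(sums.to_numpy() > 0, scale / np.where(sums > 0, sums, 1.0), 0.0)
    return expr * factors


def gini_coefficient(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector (0 = uniform, ->1 = concentrated).

    Computed as mean absolute difference over twice the mean; returns 0 for an
    all-zero vector.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = x.mean()
    if n < 2 or mean == 0:
        return 0.0
    xs = np.sort(x)
    # sum_{i<j}|x_i-x_j| via the sorted-rank identity
    ranks = np.arange(1, n + 1)
    total_abs_diff = 2.0 * np.sum((2 * ranks - n - 1) * xs)
    return float(total_abs_diff / (2.0 * n * n * mean))


def _type_means(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean expression per gene per cell type (genes x types, types sorted)."""
    types = sorted(labels.unique())
    cols = {t: expr.loc[:, labels.index[labels == t]].mean(axis=1) for t in types}
    return pd.DataFrame(cols)


def rank_markers_gini(expr: pd.DataFrame, labels: pd.Series) -> dict[str, pd.Series]:
    """Rank marker genes per cell type by Gini specificity x detection contrast.

    Parameters
    ----------
    expr
        Normalized genes x cells reference matrix.
    labels
        Cell-type label per cell, covering every column of ``expr``.

    Returns
    -------
    dict mapping each cell type to a Series of scores indexed by gene id,
    sorted descending; ties are broken by lexicographic gene id.

    Notes
    -----
    A cell "detects" a gene when its expression exceeds half the gene's mean
    across all cells. In sparse count data this reduces to expression > 0;
    at saturating depth (every cell with nonzero counts everywhere) a plain
    nonzero criterion would make every contrast vanish, while the
    scale-adaptive threshold keeps separating type-restricted genes from the
    background.
    """
    missing = [c for c in expr.columns if c not in labels.index]
    if missing:
        raise InputContractError(f"cells without labels: {missing[:10]}")
    labels = labels.loc[expr.columns]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise InputContractError("need at least 2 cell types to rank markers")
    for t in types:
        if (labels == t).sum() < 2:
            raise InputContractError(f"cell type {t!r} has fewer than 2 cells")

    means = _type_means(expr, labels)
    gini = means.apply(lambda row: gini_coefficient(row.to_numpy()), axis=1)

    vals = expr.to_numpy()
    detected = vals > 0.5 * vals.mean(axis=1, keepdims=True)
    ranking: dict[str, pd.Series] = {}
    for t in types:
        in_mask = (labels == t).to_numpy()
        frac_in = detected[:, in_mask].mean(axis=1)
        frac_out = detected[:, ~in_mask].mean(axis=1)
        score = pd.Series(gini.to_numpy() * (frac_in - frac_out), index=expr.index)
        order = sorted(score.index, key=lambda g: (-score[g], g))
        ranking[t] = score.loc[order]
    return ranking


def build_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    ranking: dict[str, pd.Series],
    top_n: int = 100,
) -> pd.DataFrame:
    """Build the signature matrix S over the union of each type's top markers.

    Entry ``(g, k)`` is the mean expression of gene ``g`` over cells labelled
    ``k``; gene rows are sorted by gene id.
    """
    if top_n < 1:
        raise InputContractError("top_n must be >= 1")
    union: set[str] = set()
    for t, scores in ranking.items():
        union.update(scores.index[:top_n])
    union &= set(expr.index)
    if not union:
        raise InputContractError("marker union is empty")
    labels = labels.loc[expr.columns]
    means = _type_means(expr, labels)
    return means.loc[sorted(union)]


def marker_sets_from_signature(
    sig: pd.DataFrame,
    ranking: dict[str, pd.Series] | None = None,
    top_n: int = 100,
    marker_sets: dict[str, list[str]] | None = None,
) -> dict[str, list[str]]:
    """Per-type marker gene sets used for the enrichment scores.

    If ``marker_sets`` is supplied by the user it is returned unchanged;
    otherwise each type's ``top_n`` ranked genes are taken.
    """
    if marker_sets is not None:
        return {t: list(genes) for t, genes in marker_sets.items()}
    if ranking is None:
        raise InputContractError("either ranking or marker_sets must be given")
    return {t: list(scores.index[:top_n]) for t, scores in ranking.items()}


class GiniMarkerSelector(BaseEstimator):
    """Select cell-type marker genes and build a signature matrix.

    A scikit-learn style estimator over a cells x genes matrix.

    Parameters
    ----------
    top_n : int
        Markers kept per cell type (default 100).
    normalize : bool
        Library-size normalize the reference before ranking.
    scale : float
        Target library size when ``normalize`` is true.

    Attributes
    ----------
    ranking_ : dict[str, pandas.Series]
        Per-type descending marker scores.
    marker_sets_ : dict[str, list[str]]
        Top ``top_n`` gene ids per type.
    signature_ : pandas.DataFrame
        Signature genes x cell types mean-expression matrix.
    """

    def __init__(self, top_n: int = 100, normalize: bool = True, scale: float = 1e4):
        self.top_n = top_n
        self.normalize = normalize
        self.scale = scale

    def fit(self, X, y):
        """Fit from a cells x genes matrix ``X`` and per-cell type labels ``y``."""
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        expr = X.T  # genes x cells internal convention
        expr.index = expr.index.astype(str)
        expr.columns = expr.columns.astype(str)
        y.index = y.index.astype(str)
        if self.normalize:
            expr = normalize_library_size(expr, self.scale)
        self.ranking_ = rank_markers_gini(expr, y)
        self.marker_sets_ = marker_sets_from_signature(None, self.ranking_, self.top_n)
        self.signature_ = build_signature(expr, y, self.ranking_, self.top_n)
        return self
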