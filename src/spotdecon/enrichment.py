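"""Per-spot cell-type enrichment (PAGE) and binarized cell-type pre-selection.

For each spot the fold change of every gene against its across-spot mean is
computed; a cell type's enrichment score is then the z-like statistic

    ES = (S_m - mu) * sqrt(m) / delta

where ``S_m`` is the mean fold change of the type's ``m`` marker genes at the
spot and ``mu``, ``delta`` are the mean and (population) standard deviation of
the fold changes across all retained genes at that spot. The ES matrix is
binarized at a cutoff (default 2) to pick the cell types plausibly present at
each spot; spots where no type passes keep their single top-scoring type so
that deconvolution is always defined.

Fold change is the plain ratio (not log ratio) of expression to the gene's
across-spot mean; a ``log_fc`` option applies ``log2(ratio + 1)`` instead.
Marker genes are included in the background mean/sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import InputContractError

__all__ = ["fold_change", "page_score", "binarize", "EnrichmentMatrix", "PAGEEnrichment"]


@dataclass
class EnrichmentMatrix:
    """Cell types x spots enrichment scores with a binary presence mask.

    ``mask == (es >= cutoff)`` except at fallback spots, where the single
    top-scoring type is kept despite falling below the cutoff.
    """

    es: pd.DataFrame
    mask: pd.DataFrame
    cutoff: float
    fallback: pd.Series = field(default=None)  # bool per spot: no type passed cutoff

    def __post_init__(self):
        if self.fallback is None:
            self.fallback = pd.Series(False, index=self.es.columns)


def fold_change(spot_expr: pd.DataFrame, drop_zero_mean: bool = True) -> pd.DataFrame:
    """Ratio of each gene's expression at each spot to its mean over spots.

    Genes whose across-spot mean is zero carry no contrast and are dropped
    with a warning. Row means of the result are identically 1.
    """
    if spot_expr.shape[1] < 2:
        raise InputContractError("fold change needs at least 2 spots")
    means = spot_expr.mean(axis=1)
    zero = means == 0
    if zero.any():
        if drop_zero_mean:
            warnings.warn(
                f"dropping {int(zero.sum())} gene(s) with zero mean across spots",
                stacklevel=2,
            )
            spot_expr = spot_expr.loc[~zero]
            means = means.loc[~zero]
        else:
            raise InputContractError("genes with zero mean across spots present")
    if spot_expr.empty:
        raise InputContractError("no genes left after zero-mean filtering")
    return spot_expr.div(means, axis=0)


def page_score(
    fc: pd.DataFrame, marker_sets: dict[str, list[str]], log_fc: bool = False
) -> pd.DataFrame:
    """PAGE enrichment scores (cell types x spots) from a fold-change matrix.

    ``delta`` uses the population (ddof=0) standard deviation. A spot with
    ``delta == 0`` (all fold changes identical) gets ES = 0 with a warning.
    Marker genes absent from ``fc`` are dropped; losing more than half of a
    set triggers a warning, losing all of it is an error.
    """
    if log_fc:
        fc = np.log2(fc + 1.0)
    vals = fc.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    delta = vals.std(axis=0, ddof=0)
    zero_sd = delta == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} spot(s) have zero fold-change sd; ES set to 0",
            stacklevel=2,
        )
    gene_index = pd.Index(fc.index)
    rows = {}
    for ctype, markers in marker_sets.items():
        markers = list(dict.fromkeys(markers))
        present = gene_index.intersection(markers)
        if len(present) == 0:
            raise InputContractError(
                f"no marker genes of type {ctype!r} found in the expression matrix"
            )
        if len(present) < 0.5 * len(markers):
            warnings.warn(
                f"type {ctype!r}: only {len(present)}/{len(markers)} markers present",
                stacklevel=2,
            )
        m = len(present)
        s_m = fc.loc[present].to_numpy().mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            es = (s_m - mu) * np.sqrt(m) / delta
        es[zero_sd] = 0.0
        rows[ctype] = es
    return pd.DataFrame(rows, index=fc.columns).T


def binarize(es: pd.DataFrame, cutoff: float = 2.0) -> EnrichmentMatrix:
    """Binarize an ES matrix at ``cutoff`` (inclusive >=).

    Spots where no cell type reaches the cutoff keep their argmax-ES type
    instead of an empty mask; those spots are flagged in ``fallback``.
    """
    if not np.isfinite(es.to_numpy()).all():
        raise InputContractError("ES matrix contains non-finite values")
    mask = es >= cutoff
    none_pass = ~mask.any(axis=0)
    for spot in es.columns[none_pass]:
        mask.loc[es[spot].idxmax(), spot] = True
    return EnrichmentMatrix(es=es, mask=mask.astype(bool), cutoff=float(cutoff),
                            fallback=none_pass.rename("fallback"))


class PAGEEnrichment(BaseEstimator, TransformerMixin):
    """Transformer computing PAGE enrichment scores for spots.

    ``fit`` stores the marker sets; ``transform`` maps a spots x genes matrix
    to a spots x cell-types ES matrix. Use :meth:`select` for the binarized
    presence mask.

    Parameters
    ----------
    marker_sets : dict[str, list[str]]
        Marker gene ids per cell type.
    cutoff : float
        ES threshold for presence (default 2).
    log_fc : bool
        Score log2(fold change + 1) instead of the plain ratio.
    """

    def __init__(self, marker_sets: dict[str, list[str]] | None = None,
                 cutoff: float = 2.0, log_fc: bool = False):
        self.marker_sets = marker_sets
        self.cutoff = cutoff
        self.log_fc = log_fc

    def fit(self, X=None, y=None):
        if self.marker_sets is None:
            raise InputContractError("marker_sets must be provided")
        self.types_ = sorted(self.marker_sets)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Spots x genes -> spots x cell types ES matrix."""
        X = pd.DataFrame(X)
        fc = fold_change(X.T)
        return page_score(fc, self.marker_sets, log_fc=self.log_fc).T

    def select(self, X) -> EnrichmentMatrix:
        """Full enrichment result (types x spots ES + binary mask)."""
        es = self.transform(X).T
        return binarize(es, self.cutoff)
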