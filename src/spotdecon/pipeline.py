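"""End-to-end estimator: reference -> signature -> enrichment -> dampened WLS.

`SpatialDWLS` follows the scikit-learn estimator contract: hyperparameters in
``__init__``, data in ``fit``/``transform``, fitted state in trailing-
underscore attributes. ``fit`` learns the cell-type signature from an
annotated single-cell reference (or accepts a precomputed signature);
``transform`` maps a spots x genes matrix to spots x cell-type fractions.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dwls import Composition, SolverConfig, cluster_spots_kmeans, deconvolve
from .enrichment import binarize, fold_change, page_score
from .io import InputContractError
from .signatures import GiniMarkerSelector, normalize_library_size

__all__ = ["SpatialDWLS"]


class SpatialDWLS(BaseEstimator, TransformerMixin):
    """Enrichment-guided dampened weighted least squares deconvolution.

    Parameters
    ----------
    signature : DataFrame, optional
        Precomputed signature (genes x cell types). If given, ``fit`` needs
        no reference data.
    marker_sets : dict, optional
        Marker gene ids per cell type for the enrichment pre-selection. If
        omitted and a reference is supplied, markers are ranked from it; if
        omitted with a precomputed signature, all signature genes of each
        type's top column are unavailable, so every type stays active.
    top_n : int
        Markers per type when ranking from a reference (default 100).
    cutoff : float
        Enrichment-score threshold for cell-type presence (default 2).
    min_frequency : float
        Types below this fraction after round one are removed (default 0.02).
    mask_level : {'cluster', 'spot'}
        Whether the enrichment pre-selection restricts types per cluster
        (union over the cluster's spots; default) or strictly per spot.
    n_clusters : int
        k for the k-means fallback when no cluster labels are passed.
    normalize, scale
        Library-size normalize inputs to a common scale (default 1e4) so the
        spots and the signature are comparable.
    damping_candidates, max_iter, tol, cv_folds, seed
        Solver parameters; see :class:`spotdecon.dwls.SolverConfig`.

    Attributes
    ----------
    signature_ : DataFrame (genes x cell types)
    marker_sets_ : dict[str, list[str]]
    enrichment_ : EnrichmentMatrix for the last transformed spots
    clusters_ : Series of spot cluster labels used in the last transform
    composition_ : Composition (fractions + per-spot diagnostics)

    Examples
    --------
    >>> est = SpatialDWLS(top_n=25, seed=0).fit(ref_cells_x_genes, cell_types)
    >>> fractions = est.transform(spots_x_genes)   # doctest: +SKIP
    """

    def __init__(
        self,
        signature: pd.DataFrame | None = None,
        marker_sets: dict[str, list[str]] | None = None,
        top_n: int = 100,
        cutoff: float = 2.0,
        min_frequency: float = 0.02,
        mask_level: str = "cluster",
        n_clusters: int = 4,
        normalize: bool = True,
        scale: float = 1e4,
        damping_candidates: tuple[float, ...] = tuple(float(2**i) for i in range(14)),
        max_iter: int = 100,
        tol: float = 1e-8,
        cv_folds: int = 10,
        seed: int = 0,
    ):
        self.signature = signature
        self.marker_sets = marker_sets
        self.top_n = top_n
        self.cutoff = cutoff
        self.min_frequency = min_frequency
        self.mask_level = mask_level
        self.n_clusters = n_clusters
        self.normalize = normalize
        self.scale = scale
        self.damping_candidates = damping_candidates
        self.max_iter = max_iter
        self.tol = tol
        self.cv_folds = cv_folds
        self.seed = seed

    def _solver_config(self) -> SolverConfig:
        return SolverConfig(
            damping_candidates=tuple(self.damping_candidates),
            max_iter=self.max_iter,
            tol=self.tol,
            min_frequency=self.min_frequency,
            cv_folds=self.cv_folds,
            seed=self.seed,
        )

    def fit(self, X=None, y=None):
        """Learn the signature and marker sets.

        ``X``: cells x genes reference matrix, ``y``: per-cell type labels —
        or both ``None`` when ``signature`` (and optionally ``marker_sets``)
        were passed as parameters.
        """
        if self.signature is not None:
            self.signature_ = self.signature.copy()
            self.marker_sets_ = (
                {t: list(g) for t, g in self.marker_sets.items()}
                if self.marker_sets is not None
                else None
            )
        else:
            if X is None or y is None:
                raise InputContractError(
                    "fit needs a reference (X, y) when no signature is given"
                )
            sel = GiniMarkerSelector(
                top_n=self.top_n, normalize=self.normalize, scale=self.scale
            ).fit(X, y)
            self.ranking_ = sel.ranking_
            self.signature_ = sel.signature_
            self.marker_sets_ = sel.marker_sets_
        return self

    def deconvolve(self, spot_expr: pd.DataFrame, clusters: pd.Series | None = None) -> Composition:
        """Deconvolve a genes x spots matrix; full diagnostics.

        ``clusters`` supplies externally computed spot cluster labels;
        otherwise a seeded k-means on top principal components is used.
        """
        if not hasattr(self, "signature_"):
            raise InputContractError("estimator is not fitted")
        if self.normalize:
            spot_expr = normalize_library_size(spot_expr, self.scale)
        if self.marker_sets_ is not None:
            fc = fold_change(spot_expr)
            es = page_score(fc, self.marker_sets_)
            enr = binarize(es, self.cutoff)
        else:
            enr = None
        if clusters is None:
            k = min(self.n_clusters, spot_expr.shape[1])
            clusters = (
                cluster_spots_kmeans(spot_expr, n_clusters=k, seed=self.seed)
                if spot_expr.shape[1] > 1
                else pd.Series("all", index=spot_expr.columns)
            )
        self.enrichment_ = enr
        self.clusters_ = clusters
        self.composition_ = deconvolve(
            spot_expr, self.signature_, enr, clusters, self._solver_config(),
            mask_level=self.mask_level,
        )
        return self.composition_

    def transform(self, X) -> pd.DataFrame:
        """Spots x genes -> spots x cell-type fractions (rows on the simplex)."""
        X = pd.DataFrame(X)
        return self.deconvolve(X.T).fractions
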