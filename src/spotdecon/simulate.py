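"""Benchmark data generation: coarse-graining and fully synthetic scenarios.

Two routes to spot-level data with known ground-truth compositions:

* :func:`coarse_grain` bins single-cell-resolution spatial data (expression,
  per-cell coordinates and type labels) into square spot-like regions —
  mimicking a lower-resolution capture array laid over an imaging dataset —
  and records the exact cell-type fractions of each bin.
* :func:`synthesize_reference` / :func:`synthesize_spots` build a fully
  synthetic annotated reference (type-specific marker genes elevated over a
  flat background, Poisson counts) and spots as Poisson-sampled mixtures of
  the per-type mean profiles on a regular grid.

All generators are bit-reproducible given a seed; ground-truth compositions
are exact rationals (cells of type / cells in bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InputContractError

__all__ = [
    "CoarseGrainResult",
    "SyntheticScenario",
    "coarse_grain",
    "synthesize_reference",
    "synthesize_spots",
    "simulate_tissue",
]


@dataclass
class CoarseGrainResult:
    """Binned spot-level data with exact ground-truth compositions."""

    spot_expr: pd.DataFrame  # genes x spots
    spot_coords: pd.DataFrame  # spot -> x, y (bin centers)
    truth: pd.DataFrame  # spots x cell types, rows sum to 1
    cells_per_spot: pd.Series
    members: dict[str, list[str]] = field(default_factory=dict)


def coarse_grain(
    expr: pd.DataFrame,
    coords: pd.DataFrame,
    labels: pd.Series,
    bin_size: float,
    aggregate: str = "sum",
    fov: pd.Series | None = None,
    min_cells: int = 1,
) -> CoarseGrainResult:
    """Bin cells into square spot-like regions and aggregate their expression.

    Cells fall into half-open square bins ``[k*b, (k+1)*b)`` on each axis,
    with the origin at the minimum coordinate of their field of view (FOV).
    Spot expression is the sum (default) or mean of member-cell expression;
    the ground truth of a spot is the exact fraction of its cells carrying
    each type label; the spot coordinate is the bin center. Bins with fewer
    than ``min_cells`` cells are dropped.
    """
    if bin_size <= 0:
        raise InputContractError("bin_size must be positive")
    if aggregate not in ("sum", "mean"):
        raise InputContractError("aggregate must be 'sum' or 'mean'")
    cells = list(expr.columns)
    missing = [c for c in cells if c not in coords.index]
    if missing:
        raise InputContractError(f"cells without coordinates: {missing[:10]}")
    missing = [c for c in cells if c not in labels.index]
    if missing:
        raise InputContractError(f"cells without labels: {missing[:10]}")
    coords = coords.loc[cells]
    labels = labels.loc[cells].astype(str)
    fov = pd.Series("0", index=cells) if fov is None else fov.loc[cells].astype(str)

    types = sorted(labels.unique())
    spot_expr_cols: dict[str, np.ndarray] = {}
    truth_rows: dict[str, np.ndarray] = {}
    coords_rows: dict[str, tuple[float, float]] = {}
    n_cells: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for f in sorted(fov.unique()):
        in_fov = fov == f
        sub = coords.loc[in_fov.index[in_fov]]
        x0, y0 = sub["x"].min(), sub["y"].min()
        ix = np.floor((sub["x"] - x0) / bin_size).astype(int)
        iy = np.floor((sub["y"] - y0) / bin_size).astype(int)
        for (bx, by), grp in sub.groupby([ix, iy]).groups.items():
            cell_ids = list(grp)
            spot = f"fov{f}_x{bx}_y{by}" if fov.nunique() > 1 else f"spot_x{bx}_y{by}"
            block = expr.loc[:, cell_ids]
            spot_expr_cols[spot] = (
                block.sum(axis=1) if aggregate == "sum" else block.mean(axis=1)
            ).to_numpy()
            lab = labels.loc[cell_ids]
            truth_rows[spot] = np.array(
                [(lab == t).sum() / len(cell_ids) for t in types]
            )
            coords_rows[spot] = (x0 + (bx + 0.5) * bin_size, y0 + (by + 0.5) * bin_size)
            n_cells[spot] = len(cell_ids)
            members[spot] = cell_ids
    keep = [s for s in spot_expr_cols if n_cells[s] >= min_cells]
    if not keep:
        raise InputContractError("no bin retained at least min_cells cells")
    spot_expr = pd.DataFrame({s: spot_expr_cols[s] for s in keep}, index=expr.index)
    truth = pd.DataFrame({s: truth_rows[s] for s in keep}, index=types).T
    spot_coords = pd.DataFrame(
        {s: coords_rows[s] for s in keep}, index=["x", "y"]
    ).T
    return CoarseGrainResult(
        spot_expr=spot_expr,
        spot_coords=spot_coords,
        truth=truth,
        cells_per_spot=pd.Series({s: n_cells[s] for s in keep}, name="n_cells"),
        members={s: members[s] for s in keep},
    )


@dataclass
class SyntheticScenario:
    """Parameters of the fully synthetic benchmark.

    Defaults emulate the coarse-grained imaging benchmark at desk scale:
    6 cell types, 60 disjoint marker genes per type elevated 10-fold over a
    flat background, 100 spots of ~7 cells each (mixtures drawn from three
    spatial regions with distinct type propensities), Poisson counts at a
    sequencing depth of 2000 transcripts per spot.
    """

    n_types: int = 6
    n_genes: int = 1000
    markers_per_type: int = 60
    n_cells_per_type: int = 50
    n_spots: int = 100
    cells_per_spot: float = 7.0
    marker_effect: float = 10.0
    depth: int = 2000
    n_regions: int = 3
    region_purity: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if self.n_types * self.markers_per_type > self.n_genes:
            raise InputContractError("marker sets exceed the gene universe")
        for name in ("n_types", "n_genes", "markers_per_type", "n_cells_per_type",
                     "n_spots", "depth", "n_regions"):
            if getattr(self, name) <= 0:
                raise InputContractError(f"{name} must be positive")
        if not 0 < self.region_purity <= 1:
            raise InputContractError("region_purity must lie in (0, 1]")

    @property
    def type_ids(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_types)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def profiles(self) -> pd.DataFrame:
        """Per-type relative expression profiles (genes x types, columns sum to 1)."""
        base = np.ones((self.n_genes, self.n_types))
        for k in range(self.n_types):
            lo = k * self.markers_per_type
            base[lo: lo + self.markers_per_type, k] = self.marker_effect
        base /= base.sum(axis=0, keepdims=True)
        return pd.DataFrame(base, index=self.gene_ids, columns=self.type_ids)

    def marker_sets(self) -> dict[str, list[str]]:
        return {
            f"type{k}": self.gene_ids[
                k * self.markers_per_type: (k + 1) * self.markers_per_type
            ]
            for k in range(self.n_types)
        }


def synthesize_reference(
    sc: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Annotated single-cell reference with planted markers (genes x cells).

    Each cell's counts are Poisson draws around its type's mean profile
    scaled to ``sc.depth`` transcripts. Returns (expression, labels, the
    planted marker sets).
    """
    rng = np.random.default_rng(sc.seed)
    profiles = sc.profiles().to_numpy()
    cols = {}
    labels = {}
    for k, t in enumerate(sc.type_ids):
        lam = profiles[:, k] * sc.depth
        for c in range(sc.n_cells_per_type):
            cid = f"{t}_cell{c}"
            cols[cid] = rng.poisson(lam)
            labels[cid] = t
    expr = pd.DataFrame(cols, index=sc.gene_ids, dtype=float)
    return expr, pd.Series(labels, name="label"), sc.marker_sets()


def _grid_coords(n: int, spacing: float = 100.0) -> pd.DataFrame:
    side = int(np.ceil(np.sqrt(n)))
    xs = [(i % side) * spacing for i in range(n)]
    ys = [(i // side) * spacing for i in range(n)]
    return pd.DataFrame({"x": xs, "y": ys}, index=[f"spot{i}" for i in range(n)])


def synthesize_spots(
    profiles: pd.DataFrame,
    compositions: pd.DataFrame,
    depth: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson-sample spot expression from mixtures of per-type profiles.

    The expected spot profile is ``sum_k f_k * profile_k`` renormalized and
    scaled to ``depth`` transcripts; spots are placed on a square grid so a
    neighbor structure exists. Returns (genes x spots expression, coords).
    """
    if ((compositions < -1e-9).any().any()
            or (np.abs(compositions.sum(axis=1) - 1) > 1e-6).any()):
        raise InputContractError("compositions must lie on the simplex")
    rng = np.random.default_rng(seed)
    P = profiles.to_numpy()
    P = P / P.sum(axis=0, keepdims=True)
    F = compositions.loc[:, profiles.columns].to_numpy()
    mean = P @ F.T  # genes x spots
    col_sums = mean.sum(axis=0, keepdims=True)
    col_sums[col_sums == 0] = 1.0
    mean = mean / col_sums * depth
    counts = rng.poisson(mean).astype(float)
    expr = pd.DataFrame(counts, index=profiles.index, columns=compositions.index)
    coords = _grid_coords(len(compositions.index))
    coords.index = compositions.index
    return expr, coords


def simulate_tissue(sc: SyntheticScenario) -> CoarseGrainResult:
    """Full synthetic tissue: spots as small cell mixtures with regional structure.

    Spots live on a square grid split into ``sc.n_regions`` vertical bands,
    mimicking layered tissue (e.g. cortical layers) where each cell type is
    spatially localized: the bands partition the cell types, and a band's
    propensity puts ``sc.region_purity`` of its mass on its own types
    (Dirichlet-jittered) and the remainder on the others. This yields
    spatially coherent compositions (positive assortativity) and natural
    per-spot absences. Each spot draws ``max(1, Poisson(cells_per_spot))``
    cells multinomially from its band's propensities; the truth is the exact
    drawn fraction. Expression is Poisson at ``sc.depth`` around the
    corresponding mixture profile.
    """
    rng = np.random.default_rng(sc.seed + 1)
    coords = _grid_coords(sc.n_spots)
    side = int(np.ceil(np.sqrt(sc.n_spots)))
    band_width = max(side / sc.n_regions, 1.0) * 100.0
    region_props = np.zeros((sc.n_regions, sc.n_types))
    for r in range(sc.n_regions):
        own = [k for k in range(sc.n_types) if k % sc.n_regions == r]
        rest = [k for k in range(sc.n_types) if k % sc.n_regions != r]
        region_props[r, own] = sc.region_purity * rng.dirichlet(np.full(len(own), 2.0))
        if rest:
            region_props[r, rest] = (1.0 - sc.region_purity) * rng.dirichlet(
                np.ones(len(rest))
            )
    truth_rows = []
    n_cells = []
    for i, spot in enumerate(coords.index):
        region = min(int(coords.loc[spot, "x"] // band_width), sc.n_regions - 1)
        n = max(1, int(rng.poisson(sc.cells_per_spot)))
        counts = rng.multinomial(n, region_props[region])
        truth_rows.append(counts / n)
        n_cells.append(n)
    truth = pd.DataFrame(truth_rows, index=coords.index, columns=sc.type_ids)
    expr, _ = synthesize_spots(sc.profiles(), truth, sc.depth, seed=sc.seed + 2)
    return CoarseGrainResult(
        spot_expr=expr,
        spot_coords=coords,
        truth=truth,
        cells_per_spot=pd.Series(n_cells, index=coords.index, name="n_cells"),
    )
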