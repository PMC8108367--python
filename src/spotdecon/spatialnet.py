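"""Spatial neighbor networks over spots and fractional composition assortativity.

The assortativity coefficient quantifies how much more often neighboring
spots share cell types than expected by chance. With ``w_k^i`` the fraction
of type ``k`` at spot ``i`` and ``e_ij`` the symmetric adjacency indicator,

    q_kk = (sum_i sum_j w_k^i w_k^j e_ij) / (sum_i sum_j e_ij)
    a_k  = (1/N) sum_i w_k^i
    Q    = (sum_k q_kk - sum_k a_k^2) / (1 - sum_k a_k^2)

Sums run over ordered pairs; the double counting of each undirected edge
cancels in the ratio, so an undirected edge list is used internally. ``N`` is
the number of spots in the network — isolated spots count toward ``a_k`` but
contribute nothing to ``q_kk``. With one-hot rows the diagonal term reduces
to the fraction of within-type edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.spatial.distance import pdist, squareform

from .dwls import NumericalError
from .io import InputContractError

__all__ = [
    "SpatialNetwork",
    "AssortativityResult",
    "build_neighbor_network",
    "assortativity",
    "assortativity_trend",
]


@dataclass
class SpatialNetwork:
    """Undirected edge set over spots (no self-loops)."""

    spot_ids: list[str]
    edges: set[tuple[str, str]]  # each pair stored sorted
    rule: str

    def __post_init__(self):
        known = set(self.spot_ids)
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise InputContractError(f"self-loop on spot {a!r}")
            if a not in known or b not in known:
                raise InputContractError(f"edge references unknown spot: ({a!r}, {b!r})")
            norm.add((a, b) if a <= b else (b, a))
        self.edges = norm

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class AssortativityResult:
    Q: float
    a: pd.Series  # per-type mean fraction, sums to 1
    q_kk: pd.Series
    n_edges: int


def build_neighbor_network(
    coords: pd.DataFrame, rule: str = "grid", param: float | None = None
) -> SpatialNetwork:
    """Connect spots that are immediately next to each other.

    rule='grid' (default): centers within ``param`` (default 1.05) times the
    minimum positive pairwise distance — captures rook/hex neighbors on
    regular arrays. rule='radius': absolute distance cutoff ``param``.
    rule='delaunay': edges of the Delaunay triangulation.
    """
    ids = list(coords.index.astype(str))
    if len(ids) < 2:
        raise InputContractError("need at least 2 spots to build a network")
    pts = coords[["x", "y"]].to_numpy(dtype=float)
    edges: set[tuple[str, str]] = set()
    if rule in ("grid", "radius"):
        dists = squareform(pdist(pts))
        positive = dists[dists > 0]
        if rule == "grid":
            if positive.size == 0:
                raise InputContractError("all spots coincide; grid rule undefined")
            cutoff = (1.05 if param is None else float(param)) * positive.min()
        else:
            if param is None:
                raise InputContractError("radius rule requires a distance cutoff")
            cutoff = float(param)
        ii, jj = np.nonzero((dists <= cutoff) & (dists > 0))
        for i, j in zip(ii, jj):
            if i < j:
                edges.add((ids[i], ids[j]) if ids[i] <= ids[j] else (ids[j], ids[i]))
    elif rule == "delaunay":
        if np.allclose(pdist(pts), 0):
            raise InputContractError("all spots coincide; triangulation undefined")
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i, j in ((0, 1), (1, 2), (0, 2)):
                a, b = ids[simplex[i]], ids[simplex[j]]
                edges.add((a, b) if a <= b else (b, a))
    else:
        raise InputContractError(f"unknown neighbor rule: {rule!r}")
    return SpatialNetwork(spot_ids=ids, edges=edges, rule=rule)


def assortativity(comp: pd.DataFrame, net: SpatialNetwork) -> AssortativityResult:
    """Fractional-weight assortativity of cell-type composition on a network.

    ``comp`` rows (one per spot, covering every network spot) must lie on the
    simplex. Raises :class:`NumericalError` when the chance term
    ``1 - sum_k a_k^2`` vanishes (a single type everywhere).
    """
    missing = [s for s in net.spot_ids if s not in comp.index]
    if missing:
        raise InputContractError(f"network spots missing from composition: {missing[:10]}")
    W = comp.loc[net.spot_ids]
    arr = W.to_numpy(dtype=float)
    if (arr < -1e-9).any() or (np.abs(arr.sum(axis=1) - 1) > 1e-6).any():
        raise InputContractError("composition rows must lie on the simplex")
    if net.n_edges == 0:
        raise NumericalError("network has no edges; q_kk undefined")
    a = W.mean(axis=0)
    pos = {s: i for i, s in enumerate(net.spot_ids)}
    num = np.zeros(arr.shape[1])
    for s1, s2 in sorted(net.edges):  # fixed order: bit-reproducible across processes
        num += arr[pos[s1]] * arr[pos[s2]]
    q_kk = pd.Series(num / net.n_edges, index=W.columns)  # 2x top / 2x bottom cancels
    chance = float((a**2).sum())
    denom = 1.0 - chance
    if abs(denom) < 1e-12:
        raise NumericalError("assortativity undefined: a single cell type everywhere")
    Q = (float(q_kk.sum()) - chance) / denom
    return AssortativityResult(Q=Q, a=a.rename("a_k"), q_kk=q_kk.rename("q_kk"),
                               n_edges=net.n_edges)


def assortativity_trend(
    comps: list[pd.DataFrame],
    nets: list[SpatialNetwork],
    group_labels: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample Q plus per-group means (e.g. developmental stages).

    Returns (per-sample table with columns ``group`` and ``Q``, per-group
    mean Q).
    """
    if not comps or not (len(comps) == len(nets) == len(group_labels)):
        raise InputContractError("comps, nets and group_labels must be equal-length, non-empty")
    qs = [assortativity(c, n).Q for c, n in zip(comps, nets)]
    table = pd.DataFrame({"group": group_labels, "Q": qs},
                         index=[f"sample{i}" for i in range(len(qs))])
    return table, table.groupby("group")["Q"].mean().rename("mean_Q")
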