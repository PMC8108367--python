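"""Dampened weighted least squares deconvolution of spot-level expression.

Each spot's expression vector ``t`` over the signature genes is modelled as a
non-negative mixture of cell-type signatures, ``t ~ S f`` with ``f`` on the
probability simplex. The fit minimises a weighted squared residual

    min_f  sum_g w_g (S f - t)_g^2    s.t.  f >= 0,  sum_k f_k = 1,

where the weights approximate the inverse squared fitted values,
``w_g = 1 / (S f)_g^2``, so that the *relative* error is minimised. Because
those weights depend on the unknown ``f``, the solve is iterated from an
unweighted initial fit. To keep a few near-zero genes from dominating, raw
weights are capped at ``d`` times the minimum weight ("dampening"); the
damping constant ``d`` is chosen by a gene-subsample cross-validation that
minimises the variance of the estimated fractions.

The spot-level pipeline additionally (i) restricts each spot to the cell
types pre-selected by enrichment, (ii) shares the damping constant and the
weight vector across all spots of a cluster (fitted on the cluster's mean
profile) to reduce technical variation, and (iii) runs a second, restricted
solve after zeroing out types below a minimum frequency (default 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .enrichment import EnrichmentMatrix
from .io import InputContractError

__all__ = [
    "NumericalError",
    "SolverConfig",
    "Composition",
    "solve_constrained_wls",
    "dampened_weights",
    "select_damping",
    "deconvolve_spot",
    "deconvolve",
    "cluster_spots_kmeans",
]

_WEIGHT_EPS = 1e-12  # floor on (Sf)^2 before inversion


class NumericalError(RuntimeError):
    """A numerical step failed irrecoverably (degenerate system)."""


@dataclass
class SolverConfig:
    """Tunable parameters of the dampened WLS solver.

    damping_candidates: candidate caps d for the weight dampening, strictly
    increasing (default 2^0 .. 2^13). min_frequency: cell types below this
    fraction after the first round are removed before the second round.
    cv_folds: number of half-gene subsamples in the damping cross-validation.
    """

    damping_candidates: tuple[float, ...] = tuple(float(2**i) for i in range(14))
    max_iter: int = 100
    tol: float = 1e-8
    min_frequency: float = 0.02
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        cands = tuple(float(d) for d in self.damping_candidates)
        if any(b <= a for a, b in zip(cands, cands[1:])) or any(d <= 0 for d in cands):
            raise InputContractError("damping candidates must be positive and strictly increasing")
        if not 0 < self.min_frequency < 1:
            raise InputContractError("min_frequency must lie in (0, 1)")
        self.damping_candidates = cands


@dataclass
class Composition:
    """Deconvolution output: spots x cell-types fractions plus diagnostics.

    Every row of ``fractions`` lies on the simplex; cell types masked out by
    enrichment are exactly zero. ``flags`` records, per spot, the cluster,
    the shared damping constant, the number of solve rounds, and whether the
    enrichment fallback or the all-zero-spot fallback fired.
    """

    fractions: pd.DataFrame
    flags: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.flags is None:
            self.flags = pd.DataFrame(index=self.fractions.index)


def _qp_objective(G: np.ndarray, h: np.ndarray, f: np.ndarray) -> float:
    return float(f @ G @ f - 2.0 * h @ f)


def _kkt_polish(G: np.ndarray, h: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exact equality-constrained solve on the support of ``f``.

    Drops coordinates that come back negative (active-set refinement) and
    returns the better of the polished and the incoming point.
    """
    k = len(h)
    best = f
    best_obj = _qp_objective(G, h, f)
    support = f > 1e-9
    if not support.any():
        support = np.ones(k, dtype=bool)
    for _ in range(2 * k):
        idx = np.flatnonzero(support)
        m = len(idx)
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = 2.0 * G[np.ix_(idx, idx)]
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        rhs = np.concatenate([2.0 * h[idx], [1.0]])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        fs = sol[:m]
        if fs.min() < -1e-10 and m > 1:
            support[idx[np.argmin(fs)]] = False
            continue
        cand = np.zeros(k)
        cand[idx] = np.clip(fs, 0.0, None)
        s = cand.sum()
        if s <= 0:
            break
        cand /= s
        if _qp_objective(G, h, cand) <= best_obj + 1e-12 * max(1.0, abs(best_obj)):
            best = cand
        break
    return best


def solve_constrained_wls(
    S: np.ndarray, t: np.ndarray, w: np.ndarray | None = None
) -> np.ndarray:
    """Solve ``min_f sum_g w_g (Sf - t)_g^2`` over the probability simplex.

    Deterministic; a convex QP solved by SLSQP and polished to machine
    precision by an exact KKT solve on the active face. ``w=None`` means
    unit weights. An all-zero ``t`` returns uniform fractions.
    """
    S = np.asarray(S, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if S.ndim != 2 or S.shape[0] != t.size:
        raise InputContractError(f"shape mismatch: S {S.shape}, t {t.shape}")
    n, k = S.shape
    if k == 0:
        raise InputContractError("signature has no cell types")
    if k == 1:
        return np.array([1.0])
    if not np.any(t):
        return np.full(k, 1.0 / k)
    if w is None:
        w = np.ones(n)
    else:
        w = np.asarray(w, dtype=float).ravel()
        if w.size != n:
            raise InputContractError("weight vector length mismatch")
        if (w <= 0).any():
            raise InputContractError("weights must be strictly positive")
        w = w / w.mean()  # scale-invariant objective; keeps the QP well-conditioned
    A = S * np.sqrt(w)[:, None]
    b = t * np.sqrt(w)
    G = A.T @ A
    h = A.T @ b
    scale = max(np.abs(G).max(), 1e-300)
    G = G / scale
    h = h / scale
    x0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda f: _qp_objective(G, h, f),
        x0,
        jac=lambda f: 2.0 * (G @ f - h),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                      "jac": lambda f: np.ones(k)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    f = np.clip(res.x, 0.0, None)
    s = f.sum()
    f = f / s if s > 0 else x0
    return _kkt_polish(G, h, f)


def dampened_weights(S: np.ndarray, f: np.ndarray, d: float) -> np.ndarray:
    """Inverse-squared-fitted-value weights capped at ``d`` x the minimum weight."""
    if d <= 0:
        raise InputContractError("damping constant must be positive")
    fitted = np.asarray(S, dtype=float) @ np.asarray(f, dtype=float)
    raw = 1.0 / np.maximum(fitted**2, _WEIGHT_EPS)
    return np.minimum(raw, d * raw.min())


def deconvolve_spot(
    S: np.ndarray,
    t: np.ndarray,
    cfg: SolverConfig | None = None,
    d: float | None = None,
    fixed_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Iterated dampened WLS solve for one expression vector.

    With ``fixed_weights`` a single weighted solve is performed. Otherwise the
    fit starts from the unweighted solution and alternates weight updates and
    solves until the fractions change by less than ``cfg.tol`` (sup norm) or
    ``cfg.max_iter`` is hit. Returns the fractions and a diagnostics dict
    (``n_iter``, ``converged``, ``d``, ``all_zero``).
    """
    cfg = cfg or SolverConfig()
    S = np.asarray(S, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    info: dict = {"n_iter": 0, "converged": True, "d": d, "all_zero": not np.any(t)}
    if info["all_zero"] or S.shape[1] == 1:
        return solve_constrained_wls(S, t), info
    if fixed_weights is not None:
        return solve_constrained_wls(S, t, fixed_weights), info
    if d is None:
        d = select_damping(S, t, cfg)
        info["d"] = d
    f = solve_constrained_wls(S, t)
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        w = dampened_weights(S, f, d)
        f_new = solve_constrained_wls(S, t, w)
        if np.max(np.abs(f_new - f)) < cfg.tol:
            f = f_new
            converged = True
            break
        f = f_new
    info.update(n_iter=n_iter, converged=converged, d=d)
    return f, info


def select_damping(S: np.ndarray, t: np.ndarray, cfg: SolverConfig) -> float:
    """Choose the damping constant by gene-subsample cross-validation.

    ``cfg.cv_folds`` half-gene subsamples are drawn once (seeded) and shared
    across candidates; each candidate's score is the across-subsample
    variance of the estimated fractions, averaged over cell types. The
    smallest candidate within numerical ties wins, so the selection is
    deterministic given the seed.
    """
    S = np.asarray(S, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    n = S.shape[0]
    if n < 2 * cfg.cv_folds:
        raise InputContractError(
            f"need at least {2 * cfg.cv_folds} signature genes for {cfg.cv_folds}-fold "
            f"damping selection, got {n}"
        )
    if len(cfg.damping_candidates) == 1:
        return cfg.damping_candidates[0]
    rng = np.random.default_rng(cfg.seed)
    half = n // 2
    subsets = [rng.choice(n, size=half, replace=False) for _ in range(cfg.cv_folds)]
    best_d = cfg.damping_candidates[0]
    best_var = np.inf
    for d in cfg.damping_candidates:
        fracs = np.stack(
            [deconvolve_spot(S[idx], t[idx], cfg, d=d)[0] for idx in subsets]
        )
        var = float(fracs.var(axis=0, ddof=0).mean())
        if var < best_var - 1e-12:
            best_var, best_d = var, d
        best_var = min(best_var, var)
    return best_d


def cluster_spots_kmeans(
    spot_expr: pd.DataFrame, n_clusters: int = 4, seed: int = 0, n_pcs: int = 10
) -> pd.Series:
    """Seeded k-means on top principal components of log-normalized spots.

    A stand-in for externally supplied spot cluster labels; deterministic
    given ``seed``.
    """
    X = np.log1p(spot_expr.to_numpy(dtype=float).T)  # spots x genes
    n_spots = X.shape[0]
    n_clusters = min(n_clusters, n_spots)
    n_comp = min(n_pcs, n_spots - 1, X.shape[1]) if n_spots > 1 else 1
    if n_spots > 1 and n_comp >= 1:
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(X)
    return pd.Series(km.labels_.astype(str), index=spot_expr.columns, name="cluster")


def deconvolve(
    spot_expr: pd.DataFrame,
    sig: pd.DataFrame,
    enr: EnrichmentMatrix | None = None,
    clusters: pd.Series | None = None,
    cfg: SolverConfig | None = None,
    mask_level: str = "cluster",
) -> Composition:
    """Cluster-aware two-round dampened WLS deconvolution of all spots.

    Per cluster: the damping constant and the gene weight vector are fitted
    once on the cluster's mean expression profile over the cluster-active
    cell types (the union of the enrichment mask over the cluster's spots),
    then applied to every spot. Per spot, types estimated below
    ``cfg.min_frequency`` are removed and the weighted solve is re-run on
    the survivors.

    Parameters
    ----------
    spot_expr : genes x spots DataFrame (same scale as the signature).
    sig : signature genes x cell types DataFrame.
    enr : enrichment mask; ``None`` keeps every type active at every spot.
    clusters : spot cluster labels; ``None`` treats all spots as one cluster.
    mask_level : 'cluster' (default) solves every spot over its cluster's
        active-type union — a spot can receive a type its own enrichment
        missed, as long as some spot of the cluster carries it, with the
        minimum-frequency second round pruning spurious assignments.
        'spot' restricts each spot strictly to its own masked-in types
        (which are then the only types that can be nonzero there).
    """
    if mask_level not in ("cluster", "spot"):
        raise InputContractError("mask_level must be 'cluster' or 'spot'")
    cfg = cfg or SolverConfig()
    types = list(sig.columns)
    spots = list(spot_expr.columns)
    genes = sig.index.intersection(spot_expr.index)
    if len(genes) < 2:
        raise InputContractError("fewer than 2 signature genes found in the spatial matrix")
    S_full = sig.loc[genes]
    T = spot_expr.loc[genes]

    if enr is None:
        mask = pd.DataFrame(True, index=types, columns=spots)
        fallback = pd.Series(False, index=spots)
    else:
        missing = [s for s in spots if s not in enr.mask.columns]
        if missing:
            raise InputContractError(f"spots missing from enrichment mask: {missing[:10]}")
        mask = enr.mask.reindex(index=types, columns=spots, fill_value=False)
        fallback = enr.fallback.reindex(spots, fill_value=False)
    if clusters is None:
        clusters = pd.Series("all", index=spots)
    else:
        missing = [s for s in spots if s not in clusters.index]
        if missing:
            raise InputContractError(f"spots without cluster labels: {missing[:10]}")
        clusters = clusters.loc[spots].astype(str)

    fractions = pd.DataFrame(0.0, index=spots, columns=types)
    flags = pd.DataFrame(
        {"cluster": clusters, "damping": np.nan, "rounds": 0,
         "enrichment_fallback": fallback.astype(bool), "all_zero": False}
    )
    type_arr = np.array(types)
    for cl in pd.unique(clusters):
        cl_spots = [s for s in spots if clusters[s] == cl]
        cl_mask = mask.loc[:, cl_spots]
        active = cl_mask.any(axis=1)
        act_types = type_arr[active.to_numpy()]
        if len(act_types) == 0:  # unreachable when enrichment fallback is applied
            raise NumericalError(f"cluster {cl!r} has no active cell types")
        S_c = S_full.loc[:, act_types].to_numpy()
        t_mean = T.loc[:, cl_spots].mean(axis=1).to_numpy()
        d_c = select_damping(S_c, t_mean, cfg)
        f_mean, _ = deconvolve_spot(S_c, t_mean, cfg, d=d_c)
        w_c = dampened_weights(S_c, f_mean, d_c)
        flags.loc[cl_spots, "damping"] = d_c
        for s in cl_spots:
            if mask_level == "cluster":
                spot_types = act_types
            else:
                spot_types = type_arr[mask[s].to_numpy()]
            S_s = S_full.loc[:, spot_types].to_numpy()
            t_s = T[s].to_numpy()
            if not np.any(t_s):
                fractions.loc[s, spot_types] = 1.0 / len(spot_types)
                flags.loc[s, ["all_zero", "rounds"]] = True, 1
                continue
            f1 = solve_constrained_wls(S_s, t_s, w_c)
            keep = f1 >= cfg.min_frequency
            if not keep.any():
                keep[np.argmax(f1)] = True
            if keep.all():
                f2, rounds = f1, 1
            else:
                f2 = solve_constrained_wls(S_s[:, keep], t_s, w_c)
                rounds = 2
            fractions.loc[s, spot_types[keep]] = f2
            flags.loc[s, "rounds"] = rounds
    return Composition(fractions=fractions, flags=flags)
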