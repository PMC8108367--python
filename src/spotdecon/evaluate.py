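"""Scoring deconvolution output against ground truth.

Per cell type the root mean square error over spots is reported, and
additionally decomposed over the spots where the type is truly present
(sensitivity) versus truly absent (specificity). Presence means a strictly
positive true fraction — ground truths from cell binning are exact rationals,
so no tolerance is involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import InputContractError

__all__ = ["rmse", "rmse_by_presence", "plot_truth_vs_estimate"]


def _align(truth: pd.DataFrame, est: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    spot_diff = set(truth.index) ^ set(est.index)
    type_diff = set(truth.columns) ^ set(est.columns)
    if spot_diff or type_diff:
        raise InputContractError(
            f"truth/estimate universes differ — spots: {sorted(spot_diff)[:10]}, "
            f"types: {sorted(type_diff)[:10]}"
        )
    return truth, est.loc[truth.index, truth.columns]


def rmse(truth: pd.DataFrame, est: pd.DataFrame) -> pd.Series:
    """Per-cell-type RMSE between two spots x types composition matrices."""
    truth, est = _align(truth, est)
    sq = (truth - est) ** 2
    return np.sqrt(sq.mean(axis=0)).rename("rmse")


def rmse_by_presence(truth: pd.DataFrame, est: pd.DataFrame) -> pd.DataFrame:
    """RMSE decomposed by true presence (> 0) vs absence of each cell type.

    Returns a DataFrame indexed by cell type with columns ``rmse``,
    ``rmse_present``, ``rmse_absent``, ``n_present``, ``n_absent``; a subset
    RMSE is NaN when its subset is empty. The exact identity
    ``n * MSE == n_present * MSE_present + n_absent * MSE_absent`` holds.
    """
    truth, est = _align(truth, est)
    rows = {}
    for t in truth.columns:
        err2 = (truth[t] - est[t]) ** 2
        present = truth[t] > 0
        n_p, n_a = int(present.sum()), int((~present).sum())
        rows[t] = {
            "rmse": float(np.sqrt(err2.mean())),
            "rmse_present": float(np.sqrt(err2[present].mean())) if n_p else np.nan,
            "rmse_absent": float(np.sqrt(err2[~present].mean())) if n_a else np.nan,
            "n_present": n_p,
            "n_absent": n_a,
        }
    report = pd.DataFrame(rows).T
    report[["n_present", "n_absent"]] = report[["n_present", "n_absent"]].astype(int)
    report.index.name = "cell_type"
    return report


def plot_truth_vs_estimate(truth: pd.DataFrame, est: pd.DataFrame, path: str) -> None:
    """Scatter of true vs estimated fraction per spot, one panel per cell type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    truth, est = _align(truth, est)
    types = list(truth.columns)
    ncol = min(3, len(types))
    nrow = int(np.ceil(len(types) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
    for ax, t in zip(axes.ravel(), types):
        ax.scatter(truth[t], est[t], s=10, alpha=0.6)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(t, fontsize=9)
        ax.set_xlabel("true fraction")
        ax.set_ylabel("estimated fraction")
    for ax in axes.ravel()[len(types):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
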