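"""Readers and writers for expression matrices, coordinate/label tables and compositions.

In-memory conventions
---------------------
* Expression matrices are :class:`pandas.DataFrame` with **genes as rows** and
  samples (cells or spots) as columns, regardless of the on-disk layout.
* Coordinate tables are DataFrames indexed by sample id with columns ``x``, ``y``
  (platform units — pixels or micrometres).
* Label tables are :class:`pandas.Series` of categorical strings indexed by
  sample id (cell type, or spot cluster).
* Composition matrices are DataFrames with **spots as rows** and cell types as
  columns; every row lies on the probability simplex.

Identifiers are the only join key: no function reorders rows or columns
silently, and duplicate identifiers are a hard error.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "InputContractError",
    "read_expression",
    "write_expression",
    "read_coordinates",
    "read_labels",
    "read_composition",
    "write_composition",
    "validate_expression",
]


class InputContractError(ValueError):
    """An input violates a documented precondition (bad file, bad matrix)."""


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def validate_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, finite non-negative values."""
    dup_genes = values.index[values.index.duplicated()].unique().tolist()
    if dup_genes:
        raise InputContractError(f"duplicate gene ids: {dup_genes}")
    dup_samples = values.columns[values.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise InputContractError(f"duplicate sample ids: {dup_samples}")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise InputContractError("expression matrix contains non-finite entries")
    if (arr < 0).any():
        bad = values.index[(arr < 0).any(axis=1)].tolist()[:10]
        raise InputContractError(f"negative expression entries in genes: {bad}")
    return values


def _read_names(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    path: str | os.PathLike,
    fmt: str = "auto",
    *,
    gene_names: str | os.PathLike | None = None,
    sample_names: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Read an expression matrix as a genes x samples DataFrame.

    Parameters
    ----------
    path
        Dense delimited table (TSV/CSV, first column = gene id, header row =
        sample ids) or a MatrixMarket ``.mtx`` triplet file.
    fmt
        ``"dense"``, ``"mtx"`` or ``"auto"`` (by file extension).
    gene_names, sample_names
        Sidecar name files (one id per line), required for ``mtx``. If the
        stored matrix is samples x genes it is transposed to match the names.
    """
    if fmt == "auto":
        fmt = "mtx" if str(path).endswith(".mtx") else "dense"
    if fmt == "dense":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str)
        return validate_expression(df)
    if fmt == "mtx":
        if gene_names is None or sample_names is None:
            raise InputContractError(
                "MatrixMarket input requires gene_names and sample_names sidecar files"
            )
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_names(gene_names)
        samples = _read_names(sample_names)
        if mat.shape == (len(genes), len(samples)):
            pass
        elif mat.shape == (len(samples), len(genes)):
            mat = mat.T
        else:
            raise InputContractError(
                f"matrix shape {mat.shape} matches neither (genes={len(genes)}, "
                f"samples={len(samples)}) nor its transpose"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
        return validate_expression(df)
    raise InputContractError(f"unknown expression format: {fmt!r}")


def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a genes x samples matrix as a delimited table."""
    validate_expression(expr)
    expr.to_csv(path, sep=_sep_for(path), float_format="%.10g", index_label="gene")


def read_coordinates(path: str | os.PathLike) -> pd.DataFrame:
    """Read a coordinate table (id, x, y; header row) indexed by sample id."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 3:
        raise InputContractError("coordinate table needs at least 3 columns: id, x, y")
    out = pd.DataFrame(
        {
            "x": pd.to_numeric(df.iloc[:, 1]).to_numpy(),
            "y": pd.to_numeric(df.iloc[:, 2]).to_numpy(),
        },
        index=df.iloc[:, 0].astype(str),
    )
    out.index.name = "sample"
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise InputContractError(f"duplicate sample ids in coordinates: {dups}")
    if not np.isfinite(out.to_numpy()).all():
        raise InputContractError("non-finite coordinates")
    return out


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column (id, label) table as a Series indexed by sample id."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise InputContractError("label table needs 2 columns: id, label")
    labels = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str), name="label"
    )
    labels.index.name = "sample"
    if labels.index.duplicated().any():
        dups = labels.index[labels.index.duplicated()].unique().tolist()
        raise InputContractError(f"duplicate sample ids in labels: {dups}")
    if labels.nunique() < 1:
        raise InputContractError("label table has no labels")
    return labels


def write_composition(comp: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a spots x cell-types composition table.

    Values round-trip through :func:`read_composition` to at least 6
    significant digits; all-zero columns are retained.
    """
    comp.to_csv(path, sep=_sep_for(path), float_format="%.10g", index_label="spot")


def read_composition(path: str | os.PathLike) -> pd.DataFrame:
    """Read a spots x cell-types composition table written by :func:`write_composition`."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def read_marker_sets(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read per-type marker gene sets from a two-column (cell_type, gene_id) table."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise InputContractError("marker table needs 2 columns: cell_type, gene_id")
    sets: dict[str, list[str]] = {}
    for ctype, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        sets.setdefault(ctype, []).append(gene)
    return sets


def write_marker_sets(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    rows = [(t, g) for t in sets for g in sets[t]]
    pd.DataFrame(rows, columns=["cell_type", "gene_id"]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_labels(labels: pd.Series, path: str | os.PathLike) -> None:
    labels.rename("label").to_csv(path, sep=_sep_for(path), index_label="sample")


def write_coordinates(coords: pd.DataFrame, path: str | os.PathLike) -> None:
    coords[["x", "y"]].to_csv(path, sep=_sep_for(path), index_label="sample")
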