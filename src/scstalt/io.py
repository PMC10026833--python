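"""On-disk artifacts: expression matrices, pseudotime tables, kernels, transfers.

Matrix-Market triplets follow the CellRanger-style layout (``matrix.mtx`` with
``features.tsv`` / ``barcodes.tsv`` sidecars, genes as rows); dense matrices
are tab-delimited with gene rows and a cell-id header. All text is UTF-8 and
floats are written with ``repr``-level precision so write/read round-trips are
lossless.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError

Layer = Literal["counts", "lognorm"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids)
        dupes = sorted(dupes[dupes.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:10]}")


@dataclass
class ExpressionMatrix:
    """A gene-by-cell expression matrix with identifiers and a layer tag.

    ``values`` is a dense ``(n_genes, n_cells)`` float array. A ``counts``
    layer must contain non-negative integers; a ``lognorm`` layer holds
    log1p-normalized expression (see :func:`scstalt.kernel.log_normalize`).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: Layer = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.layer == "counts":
            if np.any(self.values < 0):
                raise ValidationError("counts layer contains negative entries")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts layer contains non-integer entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        """Return a column-subset matrix (boolean mask or cell-id sequence)."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            cols = np.flatnonzero(arr)
        else:
            index = {c: i for i, c in enumerate(self.cell_ids)}
            missing = [c for c in arr if c not in index]
            if missing:
                raise ValidationError(f"unknown cell ids: {missing[:10]}")
            cols = np.array([index[c] for c in arr], dtype=int)
        return ExpressionMatrix(
            self.values[:, cols], self.gene_ids, self.cell_ids[cols], self.layer
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def read_expression(
    path: str | os.PathLike,
    format: Literal["mtx_triplet", "dense_delim"] = "mtx_triplet",
    layer: Layer = "counts",
    genes_are_rows: bool | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``mtx_triplet``: ``path`` is the directory holding ``matrix.mtx``,
    ``features.tsv`` and ``barcodes.tsv`` (or the ``matrix.mtx`` file itself).
    Orientation is auto-detected from the id-file lengths unless
    ``genes_are_rows`` is given explicitly.

    ``dense_delim``: tab-delimited text, gene rows, first column gene ids,
    header row of cell ids.
    """
    path = Path(path)
    if format == "mtx_triplet":
        if path.is_dir():
            mtx, feat, barc = path / "matrix.mtx", path / "features.tsv", path / "barcodes.tsv"
        else:
            mtx = path
            feat = path.parent / "features.tsv"
            barc = path.parent / "barcodes.tsv"
        for p in (mtx, feat, barc):
            if not p.exists():
                raise FormatError(f"missing triplet file: {p}")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # scipy raises ValueError on malformed headers
            raise FormatError(f"could not parse {mtx}: {exc}") from exc
        mat = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        genes = pd.read_csv(feat, sep="\t", header=None).iloc[:, 0].to_numpy(dtype=object)
        cells = pd.read_csv(barc, sep="\t", header=None).iloc[:, 0].to_numpy(dtype=object)
        if genes_are_rows is None:
            if mat.shape == (len(genes), len(cells)):
                genes_are_rows = True
            elif mat.shape == (len(cells), len(genes)):
                genes_are_rows = False
            else:
                raise FormatError(
                    f"matrix shape {mat.shape} matches neither "
                    f"({len(genes)} genes, {len(cells)} cells) nor its transpose"
                )
        if not genes_are_rows:
            mat = mat.T
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match id files "
                f"({len(genes)} features, {len(cells)} barcodes)"
            )
        return ExpressionMatrix(mat, genes, cells, layer)
    elif format == "dense_delim":
        if not path.exists():
            raise FormatError(f"missing file: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            layer,
        )
    raise ValueError(f"unknown format: {format!r}")


def write_expression(
    expr: ExpressionMatrix,
    path: str | os.PathLike,
    format: Literal["mtx_triplet", "dense_delim"] = "mtx_triplet",
) -> None:
    """Write an expression matrix; inverse of :func:`read_expression`."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(expr.values)
        if expr.layer == "counts":
            sparse = sparse.astype(np.int64)
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        pd.Series(expr.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(expr.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "dense_delim":
        path.parent.mkdir(parents=True, exist_ok=True)
        expr.to_frame().to_csv(path, sep="\t", float_format=None)
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_pseudotime(path: str | os.PathLike) -> pd.Series:
    """Read a two-column TSV (cell_id, pseudotime) into a Series indexed by cell.

    Raises on duplicate cell ids and on non-finite or non-numeric pseudotime.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, pseudotime)")
    # tolerate an optional header row
    first = df.iloc[0, 1]
    if isinstance(first, str):
        try:
            float(first)
        except ValueError:
            df = df.iloc[1:]
    cells = df.iloc[:, 0].to_numpy(dtype=object)
    _check_unique(cells, "cell")
    try:
        t = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric pseudotime: {exc}") from exc
    if not np.all(np.isfinite(t)):
        raise ValidationError(f"{path}: pseudotime contains non-finite values")
    return pd.Series(t, index=cells, name="pseudotime")


def write_pseudotime(t: pd.Series, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_id\tpseudotime\n")
        for cell, value in t.items():
            fh.write(f"{cell}\t{float(value)!r}\n")


def write_kernel(kernel, path: str | os.PathLike) -> None:
    """Kernel TSV: header row = stage-grid pseudotimes, one row per gene."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(repr(float(s)) for s in kernel.stage_grid) + "\n")
        for gene, row in zip(kernel.genes, kernel.R):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_kernel(path: str | os.PathLike):
    from .kernel import KernelProfile

    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        grid = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"{path}: kernel header must hold stage pseudotimes") from exc
    return KernelProfile(
        genes=df.index.to_numpy(dtype=object), stage_grid=grid, R=df.to_numpy(dtype=float)
    )


def write_transfer(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Transfer TSV: cell_id, stage_index, pseudotime, similarity, passed_cutoff."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = ["cell_id", "stage_index", "pseudotime", "similarity", "passed_cutoff"]
    results.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_transfer(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    return pd.read_csv(path, sep="\t")


def write_manifest(out_dir: str | os.PathLike, command: str, config: dict) -> Path:
    """Record command, config, seed and package version alongside outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "scstalt",
        "version": __version__,
        "config": _jsonable(config),
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
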