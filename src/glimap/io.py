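"""Readers and writers for expression matrices, coordinates, and model archives.

Supported on-disk formats: delimited text (TSV/CSV, genes in rows, header row of
observation ids), Matrix Market triplets with sidecar id files, and a
coordinate table with columns ``position_id, x, y[, z][, prior_mass]``. Fitted
artifacts round-trip through a ``.npz`` archive plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, InvalidDataError, SpatialReference


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path, *, gene_file: str | Path | None = None,
                           obs_file: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or Matrix Market.

    For ``.mtx`` input, ``gene_file`` and ``obs_file`` give one identifier per
    line for rows (genes) and columns (observations).
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if gene_file is None or obs_file is None:
            raise InvalidDataError("mtx input requires gene_file and obs_file")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(gene_file).read_text().split()
        obs = Path(obs_file).read_text().split()
        return ExpressionMatrix(np.asarray(mat, dtype=float), genes, obs)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExpressionMatrix.from_frame(df)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    em.to_frame().to_csv(path, sep=_sep_for(path))


def read_coordinates(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Read a coordinate table.

    Returns ``(position_ids, coords, prior_mass)``; ``prior_mass`` is None when
    the table has no ``prior_mass`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "position_id" not in cols or "x" not in cols or "y" not in cols:
        raise InvalidDataError("coordinate table needs position_id, x, y columns")
    ids = [str(v) for v in df["position_id"]]
    axes = ["x", "y"] + (["z"] if "z" in cols else [])
    coords = df[axes].to_numpy(dtype=float)
    mass = df["prior_mass"].to_numpy(dtype=float) if "prior_mass" in cols else None
    return ids, coords, mass


def write_coordinates(ref: SpatialReference, path: str | Path) -> None:
    path = Path(path)
    data = {"position_id": ref.position_ids}
    for i, ax in enumerate("xyz"[: ref.coords.shape[1]]):
        data[ax] = ref.coords[:, i]
    if ref.prior_mass is not None:
        data["prior_mass"] = ref.prior_mass
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def read_spatial_reference(expr_path: str | Path, coords_path: str | Path, *,
                           is_binary: bool = False,
                           gene_file: str | Path | None = None,
                           obs_file: str | Path | None = None) -> SpatialReference:
    """Assemble a :class:`SpatialReference` from an expression file + coordinate table.

    Positions are reordered to the expression matrix's column order; every
    expression column must appear in the coordinate table.
    """
    expr = read_expression_matrix(expr_path, gene_file=gene_file, obs_file=obs_file)
    ids, coords, mass = read_coordinates(coords_path)
    index = {p: i for i, p in enumerate(ids)}
    missing = [p for p in expr.obs_ids if p not in index]
    if missing:
        raise InvalidDataError(f"positions missing coordinates: {missing[:5]}")
    order = [index[p] for p in expr.obs_ids]
    return SpatialReference(
        expr, coords[order], None if mass is None else mass[order], is_binary
    )


def save_archive(path: str | Path, arrays: dict[str, np.ndarray],
                 meta: dict) -> None:
    """Save arrays to ``path`` (.npz) with JSON metadata at ``path + .json``."""
    path = Path(path)
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_archive(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return arrays, meta
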