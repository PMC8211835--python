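"""Core data containers: expression matrices and spatial reference atlases.

An :class:`ExpressionMatrix` is a dense genes x observations matrix with string
identifiers on both axes; it holds either an scRNA-seq query (observations are
dissociated cells) or an ISH reference payload (observations are tissue
positions). A :class:`SpatialReference` bundles the reference payload with the
per-position spatial coordinates and optional prior masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class InvalidDataError(ValueError):
    """Raised when an input matrix violates a container invariant."""


class AlignmentError(ValueError):
    """Raised when two datasets cannot be aligned on shared landmark genes."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidDataError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x observations expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_obs)
        Expression values, arbitrary (typically log-scale) units.
    gene_ids : sequence of str
        Unique row identifiers.
    obs_ids : sequence of str
        Unique column identifiers (cell barcodes or position ids).
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidDataError("values must be a 2-D matrix")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        self.obs_ids = _check_ids(self.obs_ids, "obs_ids")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise InvalidDataError(
                f"shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.obs_ids)} obs)"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidDataError("values contain non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes``, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.obs_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.obs_ids == other.obs_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SpatialReference:
    """ISH reference: landmark expression + per-position coordinates.

    Attributes
    ----------
    expr : ExpressionMatrix
        Landmark genes x positions payload.
    coords : ndarray of shape (n_positions, 2 or 3)
        Spatial coordinates of each position, same order as ``expr.obs_ids``.
    prior_mass : ndarray or None
        Optional nonnegative per-position prior masses (e.g. zone areas); used
        for the ``fixed_mass`` mixture-weight convention.
    is_binary : bool
        True when the payload is a binarized atlas (values in {0, 1}).
    """

    expr: ExpressionMatrix
    coords: np.ndarray
    prior_mass: np.ndarray | None = None
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise InvalidDataError("coords must be (n_positions, 2 or 3)")
        if self.coords.shape[0] != self.expr.n_obs:
            raise InvalidDataError(
                f"{self.coords.shape[0]} coordinates for {self.expr.n_obs} positions"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InvalidDataError("coords contain non-finite entries")
        if self.prior_mass is not None:
            self.prior_mass = np.asarray(self.prior_mass, dtype=float)
            if self.prior_mass.shape != (self.expr.n_obs,):
                raise InvalidDataError("prior_mass length must equal n_positions")
            if np.any(self.prior_mass < 0) or self.prior_mass.sum() <= 0:
                raise InvalidDataError("prior_mass must be >= 0 with positive sum")
        if self.is_binary and not np.isin(self.expr.values, (0.0, 1.0)).all():
            raise InvalidDataError("is_binary set but payload is not {0,1}-valued")

    @property
    def n_positions(self) -> int:
        return self.expr.n_obs

    @property
    def position_ids(self) -> list[str]:
        return list(self.expr.obs_ids)

    def subset_genes(self, genes: Sequence[str]) -> "SpatialReference":
        return SpatialReference(
            self.expr.subset_genes(genes),
            self.coords.copy(),
            None if self.prior_mass is None else self.prior_mass.copy(),
            self.is_binary,
        )

    def drop_gene(self, gene: str) -> "SpatialReference":
        """Return a reference with ``gene`` removed (leave-one-gene-out)."""
        kept = [g for g in self.expr.gene_ids if g != gene]
        if len(kept) == len(self.expr.gene_ids):
            raise KeyError(f"gene {gene!r} not in reference")
        return self.subset_genes(kept)
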