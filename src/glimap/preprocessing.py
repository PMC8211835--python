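"""Normalization, gene-wise centering, and landmark alignment.

Both modalities go through the same convention before any model fitting:
optional ``log(value + pseudo)`` transform, then subtraction of each gene's
mean across observations. Binary atlases take the same path (log of 0/1 plus
the pseudo-count is still monotone in the original value). Replicated smFISH
stacks are averaged position-wise beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AlignmentError,
    ExpressionMatrix,
    InvalidDataError,
    SpatialReference,
)


@dataclass
class PreprocessReport:
    """What preprocessing did: flagged genes and alignment drops."""

    zero_variance_genes: list[str] = field(default_factory=list)
    dropped_sc_genes: list[str] = field(default_factory=list)
    dropped_ref_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "zero_variance_genes": list(self.zero_variance_genes),
            "dropped_sc_genes": list(self.dropped_sc_genes),
            "dropped_ref_genes": list(self.dropped_ref_genes),
        }


def normalize_and_center(
    raw: ExpressionMatrix,
    log_transform: bool = False,
    pseudo: float = 1.0,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Optionally log-transform, then subtract each gene's mean expression.

    Parameters
    ----------
    raw : ExpressionMatrix
        Finite input matrix (counts or already log-normalized values).
    log_transform : bool
        Apply ``log(value + pseudo)`` before centering.
    pseudo : float
        Pseudo-count for the log transform; must be positive when the input
        contains zeros.

    Returns
    -------
    (ExpressionMatrix, PreprocessReport)
        Centered matrix with every gene row at mean zero; the report lists
        genes whose row had zero variance (they center to an all-zero row).
    """
    values = raw.values
    if log_transform:
        if pseudo < 0:
            raise InvalidDataError("pseudo-count must be nonnegative")
        if pseudo == 0 and np.any(values <= 0):
            raise InvalidDataError("pseudo-count 0 requires strictly positive values")
        shifted = values + pseudo
        if np.any(shifted <= 0):
            raise InvalidDataError("log transform saw non-positive value + pseudo")
        values = np.log(shifted)
    centered = values - values.mean(axis=1, keepdims=True)
    report = PreprocessReport(
        zero_variance_genes=[
            g for g, sd in zip(raw.gene_ids, values.std(axis=1)) if sd == 0.0
        ]
    )
    return ExpressionMatrix(centered, list(raw.gene_ids), list(raw.obs_ids)), report


def align_landmarks(
    sc: ExpressionMatrix,
    ref: SpatialReference,
    case_insensitive: bool = False,
) -> tuple[ExpressionMatrix, SpatialReference, PreprocessReport]:
    """Restrict both datasets to their shared landmark genes, identically ordered.

    Matching is exact string equality by default; with ``case_insensitive``,
    identifiers are compared case-folded (the sc spelling is kept). Shared
    genes keep the sc matrix's order.
    """
    if case_insensitive:
        ref_index = {g.casefold(): g for g in ref.expr.gene_ids}
        shared_sc = [g for g in sc.gene_ids if g.casefold() in ref_index]
        shared_ref = [ref_index[g.casefold()] for g in shared_sc]
    else:
        ref_set = set(ref.expr.gene_ids)
        shared_sc = [g for g in sc.gene_ids if g in ref_set]
        shared_ref = shared_sc
    if len(shared_sc) < 2:
        raise AlignmentError(
            f"only {len(shared_sc)} shared landmark genes (need >= 2)"
        )
    report = PreprocessReport(
        dropped_sc_genes=[g for g in sc.gene_ids if g not in set(shared_sc)],
        dropped_ref_genes=[g for g in ref.expr.gene_ids if g not in set(shared_ref)],
    )
    sc_out = sc.subset_genes(shared_sc)
    ref_out = ref.subset_genes(shared_ref)
    if case_insensitive:
        # rename reference rows to the sc spelling so downstream ids agree
        ref_out.expr.gene_ids = list(shared_sc)
    return sc_out, ref_out, report


def average_replicates(stacks: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Element-wise mean of replicate measurements over identical genes/positions."""
    if not stacks:
        raise InvalidDataError("no replicate stacks given")
    first = stacks[0]
    for s in stacks[1:]:
        if s.gene_ids != first.gene_ids or s.obs_ids != first.obs_ids:
            raise InvalidDataError("replicate stacks disagree on identifiers")
        if s.values.shape != first.values.shape:
            raise InvalidDataError("replicate stacks disagree on shape")
    mean = np.mean([s.values for s in stacks], axis=0)
    return ExpressionMatrix(mean, list(first.gene_ids), list(first.obs_ids))
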