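"""Mahalanobis-weighted spatial reconstruction of gene expression.

Each tissue position k receives a weighted average of all scRNA-seq cells;
the weight of cell n decays with the Mahalanobis distance D_nk between the
cell's metagene vector and the mapped reference mean of position k, through

    w_nk  propto  pi_k * exp(-alpha D_nk^2 - beta D_nk)

normalized over positions per cell. With alpha = 1/2, beta = 0 the weights are
exactly the mixture posterior; the hyperparameters are tuned by
cross-validation (see :mod:`glimap.tuning`). For the averaging itself the
weights are renormalized over cells within each position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .containers import ExpressionMatrix, InvalidDataError
from .em import MappingModel, _as_matrix
from .plsc import ParameterError


@dataclass
class WeightConfig:
    """Weighting-kernel hyperparameters (both nonnegative)."""

    alpha: float = 0.5
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            warnings.warn("alpha = beta = 0 makes the weights distance-blind",
                          stacklevel=2)


@dataclass
class ReconstructionResult:
    """Positions x genes reconstruction plus the weights that produced it."""

    ybar: np.ndarray          # (K, G)
    weights: np.ndarray       # (N, K), rows sum to 1
    config: WeightConfig
    gene_ids: list[str]
    position_ids: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.ybar, index=self.position_ids,
                            columns=self.gene_ids)


def mahalanobis_distances(X: np.ndarray, mu: np.ndarray,
                          sigma2: np.ndarray) -> np.ndarray:
    """(N, K) matrix of variance-scaled distances between cells and positions.

    D_nk = sqrt(sum_j (x_nj - mu_kj)^2 / sigma2_j); metagenes with large noise
    variance contribute less.
    """
    X = _as_matrix(X, "X")
    mu = _as_matrix(mu, "mu")
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ParameterError("sigma2 must be strictly positive")
    inv_sd = 1.0 / np.sqrt(sigma2)
    Xs = (X * inv_sd[:, None]).T
    Ms = (mu * inv_sd[:, None]).T
    d2 = (
        np.sum(Xs**2, axis=1)[:, None]
        - 2.0 * Xs @ Ms.T
        + np.sum(Ms**2, axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def compute_weights(D: np.ndarray, pi: np.ndarray,
                    config: WeightConfig) -> np.ndarray:
    """Softmax weights over positions for every cell, in log space.

    Rows (cells) sum to 1. Any constant offset in the exponent cancels in the
    normalization; stability comes from the log-sum-exp reduction.
    """
    D = _as_matrix(D, "D")
    if np.any(~np.isfinite(D)):
        raise InvalidDataError("distance matrix contains non-finite entries")
    pi = np.asarray(pi, dtype=float)
    with np.errstate(divide="ignore"):
        log_w = np.log(pi)[None, :] - config.alpha * D**2 - config.beta * D
    return np.exp(log_w - logsumexp(log_w, axis=1, keepdims=True))


def reconstruct_expression(Y_full: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of scRNA-seq cells per position.

    ybar_k = sum_n w_nk y_n / sum_j w_jk: each weight column is renormalized
    over cells, so only relative weights within a position matter. Returns a
    (K, G) matrix for a (G, N) input. A position whose weight column sums to
    zero gets the global cell mean, with a warning.
    """
    Y_full = _as_matrix(Y_full, "Y_full")
    weights = _as_matrix(weights, "weights")
    if np.any(weights < 0):
        raise InvalidDataError("weights must be nonnegative")
    if Y_full.shape[1] != weights.shape[0]:
        raise ParameterError("Y_full columns must match weight rows (cells)")
    col = weights.sum(axis=0)
    dead = col <= 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} position(s) received zero total weight; "
            "using the global mean", stacklevel=2,
        )
    safe = np.where(dead, 1.0, col)
    ybar = (weights.T @ Y_full.T) / safe[:, None]
    if np.any(dead):
        ybar[dead] = Y_full.mean(axis=1)
    return ybar


def reconstruct(Y_full: ExpressionMatrix, X: np.ndarray, model: MappingModel,
                config: WeightConfig,
                position_ids: list[str] | None = None) -> ReconstructionResult:
    """Full second step: distances -> weights -> weighted average.

    ``Y_full`` may contain any gene set (landmarks or the genome-wide matrix);
    the weights depend only on the metagene space and are shared by all genes.
    """
    D = mahalanobis_distances(X, model.mu, model.sigma2)
    w = compute_weights(D, model.pi, config)
    ybar = reconstruct_expression(Y_full.values, w)
    if position_ids is None:
        position_ids = [str(k) for k in range(model.n_positions)]
    return ReconstructionResult(ybar=ybar, weights=w, config=config,
                                gene_ids=list(Y_full.gene_ids),
                                position_ids=list(position_ids))


def weight_sensitivity(X: np.ndarray, model: MappingModel, weights: np.ndarray,
                       config: WeightConfig, n: int, k: int) -> np.ndarray:
    """Per-metagene derivative dw_nk/dx_ni of the weight of cell n at position k.

    Closed form w(1-w)(-2 alpha D - beta)/D * (x - mu)/sigma2: the gradient is
    inversely proportional to the noise variance, so perturbing an unreliable
    metagene barely moves the weights. The form keeps only the k-th term of
    the softmax Jacobian (the competing positions' distances are treated as
    stationary); it is a diagnostic, not used in fitting. Returns NaNs when
    D_nk = 0, where the derivative is undefined.
    """
    X = _as_matrix(X, "X")
    D = mahalanobis_distances(X[:, [n]], model.mu, model.sigma2)[0]
    d_nk = D[k]
    if d_nk == 0.0:
        warnings.warn("D_nk = 0: weight gradient undefined", stacklevel=2)
        return np.full(model.n_metagenes, np.nan)
    w = weights[n, k]
    prefactor = w * (1.0 - w) * (-2.0 * config.alpha * d_nk - config.beta) / d_nk
    return prefactor * (X[:, n] - model.mu[:, k]) / model.sigma2
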