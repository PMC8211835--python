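"""Partial least squares correlation (PLSC): shared metagene coordinates.

Both centered datasets are reduced to M "metagenes" — correlated linear
combinations of landmark genes shared between modalities — by a truncated SVD
of the cross-product matrix W = Yᵀ·H (cells x positions). Scaling the singular
vectors by the singular values yields the metagene matrices X (scRNA-seq) and
R (reference) on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix


class ParameterError(ValueError):
    """Raised for out-of-range user parameters."""


@dataclass
class MetageneSpace:
    """Truncated PLSC factorization of the cross-product matrix.

    Attributes
    ----------
    U : ndarray (M, N)
        Left singular vectors, one row per metagene, columns indexed by cells.
    V : ndarray (M, K)
        Right singular vectors, columns indexed by positions.
    delta : ndarray (M,)
        Singular values, descending, nonnegative.
    X : ndarray (M, N)
        scRNA-seq metagene matrix, ``diag(delta) @ U``.
    R : ndarray (M, K)
        Reference metagene matrix, ``diag(delta) @ V``.
    """

    U: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    R: np.ndarray

    @property
    def n_metagenes(self) -> int:
        return int(self.delta.shape[0])

    def arrays(self) -> dict[str, np.ndarray]:
        return {"U": self.U, "V": self.V, "delta": self.delta,
                "X": self.X, "R": self.R}

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "MetageneSpace":
        return cls(arrays["U"], arrays["V"], arrays["delta"],
                   arrays["X"], arrays["R"])


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD signs are arbitrary per component; make the largest-|.| entry of each
    # V row positive so repeated runs are bit-identical.
    for j in range(V.shape[0]):
        pivot = np.argmax(np.abs(V[j]))
        if V[j, pivot] < 0:
            V[j] = -V[j]
            U[j] = -U[j]
    return U, V


def plsc_reduce(Y: ExpressionMatrix | np.ndarray, H: ExpressionMatrix | np.ndarray,
                M: int) -> MetageneSpace:
    """Reduce a centered dataset pair to ``M`` metagene coordinates.

    Parameters
    ----------
    Y : (D, N) matrix
        Centered scRNA-seq landmark matrix.
    H : (D, K) matrix
        Centered reference landmark matrix (same genes, same order).
    M : int
        Number of metagenes to keep, ``1 <= M <= min(D, N, K)``.
    """
    Yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
    Hv = H.values if isinstance(H, ExpressionMatrix) else np.asarray(H, dtype=float)
    if Yv.shape[0] != Hv.shape[0]:
        raise ParameterError(
            f"gene dimensions differ: {Yv.shape[0]} vs {Hv.shape[0]}"
        )
    D, N = Yv.shape
    K = Hv.shape[1]
    limit = min(N, K)  # the SVD bound; D only limits the numerical rank
    if not (1 <= M <= limit):
        raise ParameterError(f"M={M} outside [1, min(N, K)={limit}]")
    W = Yv.T @ Hv
    Ufull, s, Vt = scipy.linalg.svd(W, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(N, K) * np.finfo(float).eps)) if s.size else 0
    if rank < M:
        warnings.warn(
            f"cross-product matrix has numerical rank {rank} < M={M}; "
            "trailing singular values are ~0",
            stacklevel=2,
        )
    U = np.array(Ufull[:, :M].T)          # (M, N)
    V = np.array(Vt[:M])                  # (M, K)
    delta = np.array(s[:M])
    if M > 1:
        gaps = np.abs(np.diff(delta))
        if delta[0] > 0 and np.any(gaps / delta[0] < 1e-8):
            warnings.warn("near-degenerate singular values; metagene order "
                          "within tied blocks is not meaningful", stacklevel=2)
    U, V = _fix_signs(U, V)
    X = delta[:, None] * U
    R = delta[:, None] * V
    return MetageneSpace(U=U, V=V, delta=delta, X=X, R=R)


def choose_m(Y: ExpressionMatrix | np.ndarray, H: ExpressionMatrix | np.ndarray,
             criterion: str = "fixed", *, m: int = 60,
             threshold: float = 0.9) -> int:
    """Pick the number of metagenes.

    criterion "fixed" returns ``m`` capped at min(D, N, K); "variance_fraction"
    returns the smallest M whose cumulative squared-singular-value share
    reaches ``threshold``; "elbow" maximizes the distance of the squared
    singular-value curve from its end-to-end chord.
    """
    Yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
    Hv = H.values if isinstance(H, ExpressionMatrix) else np.asarray(H, dtype=float)
    limit = min(Yv.shape[0], Yv.shape[1], Hv.shape[1])
    if criterion == "fixed":
        return max(1, min(int(m), limit))
    if criterion not in ("variance_fraction", "elbow"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    s = scipy.linalg.svdvals(Yv.T @ Hv)[:limit]
    energy = s**2
    total = energy.sum()
    if total == 0:
        return 1
    if criterion == "variance_fraction":
        share = np.cumsum(energy) / total
        return int(np.searchsorted(share, threshold - 1e-12) + 1)
    # elbow: farthest point from the chord through (1, e_1) .. (L, e_L)
    idx = np.arange(len(energy), dtype=float)
    chord = energy[0] + (energy[-1] - energy[0]) * idx / max(len(energy) - 1, 1)
    return int(np.argmax(energy - chord) + 1) if len(energy) > 2 else 1


def default_n_metagenes(D: int, N: int, K: int, cap: int = 60) -> int:
    """Default metagene count: ``min(cap, min(D, N, K) - 1)``, at least 1."""
    return max(1, min(cap, min(D, N, K) - 1))


class PLSC(BaseEstimator):
    """Partial least squares correlation as a paired-dataset estimator.

    Parameters
    ----------
    n_components : int or None
        Number of metagenes; None uses ``min(60, min(D, N, K) - 1)``.

    Attributes
    ----------
    space_ : MetageneSpace
        Fitted factorization.
    delta_ : ndarray (M,)
        Singular values.
    X_, R_ : ndarray
        Metagene matrices of the scRNA-seq and reference datasets.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, Y: ExpressionMatrix | np.ndarray,
            H: ExpressionMatrix | np.ndarray) -> "PLSC":
        Yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
        Hv = H.values if isinstance(H, ExpressionMatrix) else np.asarray(H, float)
        M = self.n_components
        if M is None:
            M = default_n_metagenes(Yv.shape[0], Yv.shape[1], Hv.shape[1])
        self.space_ = plsc_reduce(Yv, Hv, M)
        self.n_components_ = self.space_.n_metagenes
        self.delta_ = self.space_.delta
        self.X_ = self.space_.X
        self.R_ = self.space_.R
        return self
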