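"""Gaussian-mixture fit of the generative linear map between modalities.

The scRNA-seq metagene vectors x_n are modeled as draws from a K-component
Gaussian mixture whose component means are affine images of the reference
metagene vectors r_k:

    x ~ sum_k pi_k N(x | A r_k + b, Sigma),   A = diag(a), Sigma = diag(sigma2)

a_j is the per-metagene sensitivity of the scRNA-seq measurement relative to
the reference, b_j a background offset, and sigma2_j the (squared) noise
intensity. The diagonal structure makes every parameter update closed-form;
fitting is plain EM with a shared diagonal covariance, and the mixture weights
pi can be held fixed (uniform, or proportional to supplied position masses) or
updated by the standard EM rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .plsc import ParameterError

PI_MODES = ("fixed_uniform", "fixed_mass", "updated")


class NumericError(RuntimeError):
    """Raised when the fit produces non-finite quantities."""


@dataclass
class MappingModel:
    """Fitted generative parameters in metagene space.

    ``mu`` caches the mapped reference means ``diag(a) @ R + b`` for the
    reference used during fitting.
    """

    pi: np.ndarray        # (K,) mixture weights, sum to 1
    a: np.ndarray         # (M,) per-metagene sensitivity
    b: np.ndarray         # (M,) per-metagene background
    sigma2: np.ndarray    # (M,) per-metagene noise variance
    mu: np.ndarray        # (M, K) mapped reference means
    pi_mode: str = "fixed_uniform"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.pi_mode not in PI_MODES:
            raise ParameterError(f"pi_mode must be one of {PI_MODES}")
        if abs(self.pi.sum() - 1.0) > 1e-12 * max(1.0, self.pi.size):
            raise ParameterError("mixture weights must sum to 1")
        if np.any(self.sigma2 <= 0):
            raise ParameterError("sigma2 entries must be positive")

    @property
    def n_metagenes(self) -> int:
        return int(self.a.shape[0])

    @property
    def n_positions(self) -> int:
        return int(self.pi.shape[0])

    def arrays(self) -> dict[str, np.ndarray]:
        return {"pi": self.pi, "a": self.a, "b": self.b,
                "sigma2": self.sigma2, "mu": self.mu}

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray],
                    pi_mode: str = "fixed_uniform") -> "MappingModel":
        return cls(arrays["pi"], arrays["a"], arrays["b"], arrays["sigma2"],
                   arrays["mu"], pi_mode)


@dataclass
class SufficientStats:
    """Responsibility-weighted sums entering the closed-form M step."""

    phi: np.ndarray     # sum_nk gamma_nk x_ni
    chi: np.ndarray     # sum_nk gamma_nk r_ki
    psi: np.ndarray     # sum_nk gamma_nk x_ni r_ki
    omega: np.ndarray   # sum_nk gamma_nk r_ki^2


@dataclass
class FitTrace:
    """Per-iteration log-likelihood record of an EM run."""

    loglik_per_iter: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _as_matrix(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError(f"{name} must be a 2-D matrix")
    return X


def map_reference(model: MappingModel, R: np.ndarray) -> np.ndarray:
    """Mapped reference means ``diag(a) @ R + b`` (metagenes x positions)."""
    R = _as_matrix(R, "R")
    if R.shape[0] != model.n_metagenes:
        raise ParameterError(
            f"R has {R.shape[0]} metagenes, model has {model.n_metagenes}"
        )
    return model.a[:, None] * R + model.b[:, None]


def make_pi(pi_mode: str, K: int, prior_mass: np.ndarray | None = None) -> np.ndarray:
    """Mixture weights for a pi convention: uniform, mass-proportional, or uniform start."""
    if pi_mode not in PI_MODES:
        raise ParameterError(f"pi_mode must be one of {PI_MODES}")
    if pi_mode == "fixed_mass":
        if prior_mass is None:
            raise ParameterError("fixed_mass pi_mode requires prior_mass")
        mass = np.asarray(prior_mass, dtype=float)
        if mass.shape != (K,) or np.any(mass < 0) or mass.sum() <= 0:
            raise ParameterError("prior_mass must be K nonnegative reals, sum > 0")
        return mass / mass.sum()
    return np.full(K, 1.0 / K)


def init_params(X: np.ndarray, R: np.ndarray, pi_mode: str = "fixed_uniform",
                prior_mass: np.ndarray | None = None) -> MappingModel:
    """Moment-matching initialization.

    a_i matches the per-metagene standard deviations of X to those of R,
    b_i matches the means, and sigma2_i starts at the variance of X's row i
    (population moments, ddof 0). A zero-variance reference metagene gets
    a_i = 0, b_i = mean(x_i) with a warning.
    """
    X = _as_matrix(X, "X")
    R = _as_matrix(R, "R")
    if X.shape[0] != R.shape[0]:
        raise ParameterError("X and R must share the metagene dimension")
    if X.size == 0 or R.size == 0:
        raise ParameterError("X and R must be nonempty")
    sx = X.std(axis=1)
    sr = R.std(axis=1)
    mx = X.mean(axis=1)
    mr = R.mean(axis=1)
    zero = sr == 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance reference metagene(s); their "
            "sensitivity is initialized to 0", stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(zero, 0.0, sx / np.where(zero, 1.0, sr))
    b = mx - a * mr
    sigma2 = np.maximum(sx**2, np.finfo(float).tiny)
    pi = make_pi(pi_mode, R.shape[1], prior_mass)
    model = MappingModel(pi, a, b, sigma2, np.empty((X.shape[0], R.shape[1])),
                         pi_mode)
    model.mu = map_reference(model, R)
    return model


def _log_gauss(X: np.ndarray, model: MappingModel) -> np.ndarray:
    """(N, K) matrix of log N(x_n | mu_k, Sigma) with shared diagonal Sigma."""
    inv_sd = 1.0 / np.sqrt(model.sigma2)
    Xs = (X * inv_sd[:, None]).T          # (N, M)
    Ms = (model.mu * inv_sd[:, None]).T   # (K, M)
    # squared Mahalanobis distances via the expansion trick
    d2 = (
        np.sum(Xs**2, axis=1)[:, None]
        - 2.0 * Xs @ Ms.T
        + np.sum(Ms**2, axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    M = model.n_metagenes
    log_norm = -0.5 * (M * np.log(2.0 * np.pi) + np.sum(np.log(model.sigma2)))
    return log_norm - 0.5 * d2


def log_likelihood(X: np.ndarray, model: MappingModel) -> float:
    """Mixture log-likelihood sum_n log sum_k pi_k N(x_n | mu_k, Sigma)."""
    X = _as_matrix(X, "X")
    log_p = _log_gauss(X, model) + np.log(model.pi)[None, :]
    return float(logsumexp(log_p, axis=1).sum())


def e_step(X: np.ndarray, model: MappingModel) -> np.ndarray:
    """Responsibilities gamma_nk = P(origin k | x_n), rows summing to 1."""
    X = _as_matrix(X, "X")
    log_p = _log_gauss(X, model) + np.log(model.pi)[None, :]
    norm = logsumexp(log_p, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} data point(s) numerically unreachable by every "
            "component; assigning uniform responsibilities", stacklevel=2,
        )
        log_p[bad] = 0.0
        norm[bad] = np.log(log_p.shape[1])
    return np.exp(log_p - norm)


def sufficient_stats(X: np.ndarray, R: np.ndarray,
                     gamma: np.ndarray) -> SufficientStats:
    """Responsibility-weighted sums phi, chi, psi, omega (one per metagene)."""
    row = gamma.sum(axis=1)   # = 1 per row for valid responsibilities
    col = gamma.sum(axis=0)   # (K,)
    phi = X @ row
    chi = R @ col
    psi = np.sum((X @ gamma) * R, axis=1)
    omega = (R**2) @ col
    return SufficientStats(phi=phi, chi=chi, psi=psi, omega=omega)


def m_step(X: np.ndarray, R: np.ndarray, gamma: np.ndarray,
           pi_mode: str = "fixed_uniform", prev: MappingModel | None = None,
           sigma2_floor: np.ndarray | float = 0.0) -> MappingModel:
    """Closed-form parameter update maximizing the expected complete-data
    log-likelihood under the current responsibilities.

    The background b is updated first, then the sensitivity a (whose update
    references the new b), then sigma2 from both new values. pi is replaced by
    the column means of gamma only in ``updated`` mode. A metagene whose
    normal-equation denominator N*omega - chi^2 is numerically singular keeps
    its previous (a, b) (requires ``prev``).
    """
    X = _as_matrix(X, "X")
    R = _as_matrix(R, "R")
    gamma = _as_matrix(gamma, "gamma")
    N = X.shape[1]
    stats = sufficient_stats(X, R, gamma)
    denom = N * stats.omega - stats.chi**2
    scale = np.maximum(N * stats.omega, 1.0)
    degenerate = np.abs(denom) <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (stats.omega * stats.phi - stats.psi * stats.chi) / denom
        a = (stats.psi - stats.chi * b) / np.where(stats.omega == 0, 1.0,
                                                   stats.omega)
    if np.any(degenerate):
        if prev is None:
            raise NumericError(
                f"degenerate metagene(s) {np.flatnonzero(degenerate).tolist()} "
                "and no previous parameters to hold"
            )
        warnings.warn(
            f"metagene(s) {np.flatnonzero(degenerate).tolist()} degenerate; "
            "holding previous a, b", stacklevel=2,
        )
        b = np.where(degenerate, prev.b, b)
        a = np.where(degenerate, prev.a, a)
    # sigma2: responsibility-weighted mean squared residual, per metagene
    sigma2 = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        resid = X[i][:, None] - a[i] * R[i][None, :] - b[i]
        sigma2[i] = np.sum(gamma * resid**2) / N
    sigma2 = np.maximum(sigma2, np.maximum(sigma2_floor, np.finfo(float).tiny))
    if pi_mode == "updated":
        pi = gamma.sum(axis=0) / N
        pi = pi / pi.sum()
    elif prev is not None:
        pi = prev.pi
    else:
        pi = np.full(gamma.shape[1], 1.0 / gamma.shape[1])
    model = MappingModel(pi, a, b, sigma2, np.empty((X.shape[0], R.shape[1])),
                         pi_mode)
    model.mu = map_reference(model, R)
    return model


def q_function(X: np.ndarray, R: np.ndarray, gamma: np.ndarray,
               model: MappingModel) -> float:
    """Expected complete-data log-likelihood under responsibilities gamma."""
    X = _as_matrix(X, "X")
    log_p = _log_gauss(X, model)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    terms = gamma * (log_pi[None, :] + log_p)
    return float(np.sum(np.where(gamma > 0, terms, 0.0)))


def fit_em(X: np.ndarray, R: np.ndarray, *, pi_mode: str = "fixed_uniform",
           prior_mass: np.ndarray | None = None, max_iter: int = 1000,
           tol: float = 1e-6,
           sigma2_floor_scale: float = 1e-8) -> tuple[MappingModel, FitTrace]:
    """Fit the generative map by EM from the moment-matching start.

    Iterates E and M steps until the relative change of the log-likelihood
    falls below ``tol`` or ``max_iter`` is reached. The per-metagene noise
    variance is floored at ``sigma2_floor_scale`` times the variance of the
    corresponding X row. Deterministic: no randomness enters the fit.
    """
    X = _as_matrix(X, "X")
    R = _as_matrix(R, "R")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    if X.shape[0] != R.shape[0]:
        raise ParameterError("X and R must share the metagene dimension")
    floor = sigma2_floor_scale * np.maximum(X.var(axis=1), np.finfo(float).tiny)
    model = init_params(X, R, pi_mode, prior_mass)
    model.sigma2 = np.maximum(model.sigma2, floor)
    model.mu = map_reference(model, R)
    trace = FitTrace()
    prev_ll = -np.inf
    for it in range(max_iter):
        gamma = e_step(X, model)
        model = m_step(X, R, gamma, pi_mode, prev=model, sigma2_floor=floor)
        ll = log_likelihood(X, model)
        if not np.isfinite(ll):
            worst = int(np.argmin(model.sigma2))
            raise NumericError(
                f"non-finite log-likelihood at iteration {it} "
                f"(smallest-variance metagene: {worst})"
            )
        trace.loglik_per_iter.append(ll)
        trace.n_iter = it + 1
        if abs(ll - prev_ll) / (1.0 + abs(ll)) < tol:
            trace.converged = True
            break
        prev_ll = ll
    return model, trace


class GenerativeMapEM(BaseEstimator):
    """EM estimator of the affine metagene map, scikit-learn style.

    Parameters
    ----------
    pi_mode : {"fixed_uniform", "fixed_mass", "updated"}
        Mixture-weight convention. Fixed-uniform divides the tissue into
        equal-mass positions; fixed_mass uses supplied position masses (zone
        areas); updated re-estimates pi each iteration.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    sigma2_floor_scale : float
        Noise-variance floor as a fraction of each metagene's data variance.

    Attributes
    ----------
    model_ : MappingModel
    trace_ : FitTrace
    responsibilities_ : ndarray (N, K)
        Posterior origin probabilities of the training cells.
    """

    def __init__(self, pi_mode: str = "fixed_uniform", max_iter: int = 1000,
                 tol: float = 1e-6, sigma2_floor_scale: float = 1e-8):
        self.pi_mode = pi_mode
        self.max_iter = max_iter
        self.tol = tol
        self.sigma2_floor_scale = sigma2_floor_scale

    def fit(self, X: np.ndarray, R: np.ndarray,
            prior_mass: np.ndarray | None = None) -> "GenerativeMapEM":
        self.model_, self.trace_ = fit_em(
            X, R, pi_mode=self.pi_mode, prior_mass=prior_mass,
            max_iter=self.max_iter, tol=self.tol,
            sigma2_floor_scale=self.sigma2_floor_scale,
        )
        self.responsibilities_ = e_step(np.asarray(X, float), self.model_)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior origin probabilities of new metagene vectors."""
        return e_step(X, self.model_)

    def score(self, X: np.ndarray) -> float:
        """Total mixture log-likelihood of ``X`` under the fitted model."""
        return log_likelihood(X, self.model_)
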