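"""End-to-end estimator: preprocessing -> PLSC -> EM -> reconstruction.

:class:`SpatialGeneMapper` is the user-facing estimator. ``fit`` aligns the
two modalities on shared landmark genes, reduces them to metagenes, and fits
the generative map; ``predict`` reconstructs the spatial profile of any gene
set by Mahalanobis-weighted averaging; ``predict_origin`` returns each cell's
posterior over tissue positions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, SpatialReference
from .em import GenerativeMapEM, e_step
from .plsc import ParameterError, default_n_metagenes, plsc_reduce
from .preprocessing import align_landmarks, normalize_and_center
from .reconstruct import (
    ReconstructionResult,
    WeightConfig,
    compute_weights,
    mahalanobis_distances,
    reconstruct_expression,
)


class SpatialGeneMapper(BaseEstimator):
    """Map an scRNA-seq dataset onto an ISH spatial reference.

    Parameters
    ----------
    n_metagenes : int or None
        PLSC dimensionality; None uses ``min(60, min(D, N, K) - 1)``.
    use_plsc : bool
        When False, skip the reduction and treat each landmark gene as its own
        metagene (useful for parameter-recovery studies).
    alpha, beta : float
        Weighting-kernel hyperparameters; (1/2, 0) gives posterior weights.
    pi_mode : {"fixed_uniform", "fixed_mass", "updated"}
        Mixture-weight convention; ``fixed_mass`` uses the reference's
        per-position prior masses.
    log_transform_sc, log_transform_ref : bool
        Apply log(value + pseudo) to the respective modality before centering
        (off for already log-normalized input).
    pseudo : float
        Pseudo-count of the log transform.
    tol, max_iter, sigma2_floor_scale : EM settings.
    case_insensitive : bool
        Case-insensitive landmark matching.

    Attributes
    ----------
    landmark_genes_ : list of str
        Shared genes used for the mapping, in fit order.
    space_ : MetageneSpace or None
        PLSC factorization (None when ``use_plsc=False``).
    X_, R_ : ndarray
        Metagene matrices of cells and positions.
    model_ : MappingModel
        Fitted generative parameters.
    trace_ : FitTrace
        EM log-likelihood trajectory.
    """

    def __init__(self, n_metagenes: int | None = None, use_plsc: bool = True,
                 alpha: float = 0.5, beta: float = 0.0,
                 pi_mode: str = "fixed_uniform",
                 log_transform_sc: bool = False,
                 log_transform_ref: bool = False, pseudo: float = 1.0,
                 tol: float = 1e-6, max_iter: int = 1000,
                 sigma2_floor_scale: float = 1e-8,
                 case_insensitive: bool = False):
        self.n_metagenes = n_metagenes
        self.use_plsc = use_plsc
        self.alpha = alpha
        self.beta = beta
        self.pi_mode = pi_mode
        self.log_transform_sc = log_transform_sc
        self.log_transform_ref = log_transform_ref
        self.pseudo = pseudo
        self.tol = tol
        self.max_iter = max_iter
        self.sigma2_floor_scale = sigma2_floor_scale
        self.case_insensitive = case_insensitive

    def fit(self, sc: ExpressionMatrix, ref: SpatialReference) -> "SpatialGeneMapper":
        sc_centered, sc_report = normalize_and_center(
            sc, self.log_transform_sc, self.pseudo)
        ref_centered, ref_report = normalize_and_center(
            ref.expr, self.log_transform_ref, self.pseudo)
        ref_proc = SpatialReference(ref_centered, ref.coords, ref.prior_mass,
                                    is_binary=False)
        sc_land, ref_land, align_report = align_landmarks(
            sc_centered, ref_proc, self.case_insensitive)
        # zero-variance rows survive centering but are excluded from the
        # cross-product factorization
        flagged = set(sc_report.zero_variance_genes) | set(
            ref_report.zero_variance_genes)
        usable = [g for g in sc_land.gene_ids if g not in flagged]
        if len(usable) < 2:
            raise ParameterError("fewer than 2 usable (non-constant) landmarks")
        sc_land = sc_land.subset_genes(usable)
        ref_land = ref_land.subset_genes(usable)

        self.sc_centered_ = sc_centered
        vals = sc.values
        if self.log_transform_sc:
            vals = np.log(vals + self.pseudo)
        self.sc_gene_means_ = vals.mean(axis=1)
        self.ref_centered_ = ref_land.expr
        self.landmark_genes_ = usable
        self.cell_ids_ = list(sc.obs_ids)
        self.position_ids_ = ref.position_ids
        self.coords_ = ref.coords.copy()
        self.reports_ = {"sc": sc_report, "ref": ref_report,
                         "align": align_report}

        Y = sc_land.values
        H = ref_land.expr.values
        if self.use_plsc:
            M = self.n_metagenes
            if M is None:
                M = default_n_metagenes(Y.shape[0], Y.shape[1], H.shape[1])
            self.space_ = plsc_reduce(Y, H, M)
            self.X_ = self.space_.X
            self.R_ = self.space_.R
        else:
            self.space_ = None
            self.X_ = Y
            self.R_ = H
        em = GenerativeMapEM(pi_mode=self.pi_mode, max_iter=self.max_iter,
                             tol=self.tol,
                             sigma2_floor_scale=self.sigma2_floor_scale)
        em.fit(self.X_, self.R_, prior_mass=ref.prior_mass)
        self.em_ = em
        self.model_ = em.model_
        self.trace_ = em.trace_
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("mapper is not fitted; call fit() first")

    def weights(self, alpha: float | None = None,
                beta: float | None = None) -> np.ndarray:
        """(N, K) weight matrix at the given (or configured) hyperparameters."""
        self._check_fitted()
        cfg = WeightConfig(self.alpha if alpha is None else alpha,
                           self.beta if beta is None else beta)
        D = mahalanobis_distances(self.X_, self.model_.mu, self.model_.sigma2)
        return compute_weights(D, self.model_.pi, cfg)

    def predict(self, genes: list[str] | str = "all",
                alpha: float | None = None, beta: float | None = None,
                inverse_transform: bool = False) -> ReconstructionResult:
        """Reconstruct the spatial profile of ``genes`` (default: every sc gene).

        Output is on the centered log scale used internally; with
        ``inverse_transform`` the per-gene means are added back (and the log
        transform undone via expm1 when one was applied to the sc data).
        """
        self._check_fitted()
        cfg = WeightConfig(self.alpha if alpha is None else alpha,
                           self.beta if beta is None else beta)
        if isinstance(genes, str):
            if genes != "all":
                genes = [genes]
            else:
                genes = list(self.sc_centered_.gene_ids)
        payload = self.sc_centered_.subset_genes(list(genes))
        D = mahalanobis_distances(self.X_, self.model_.mu, self.model_.sigma2)
        w = compute_weights(D, self.model_.pi, cfg)
        ybar = reconstruct_expression(payload.values, w)
        if inverse_transform:
            means = self._gene_means(list(genes))
            ybar = ybar + means[None, :]
            if self.log_transform_sc:
                ybar = np.expm1(ybar)
        return ReconstructionResult(ybar=ybar, weights=w, config=cfg,
                                    gene_ids=list(genes),
                                    position_ids=list(self.position_ids_))

    def _gene_means(self, genes: list[str]) -> np.ndarray:
        # means removed by centering, on the (possibly log) scale
        idx = {g: i for i, g in enumerate(self.sc_centered_.gene_ids)}
        return np.array([self.sc_gene_means_[idx[g]] for g in genes])

    def predict_origin_proba(self, X: np.ndarray | None = None) -> np.ndarray:
        """Posterior origin probabilities (training cells by default)."""
        self._check_fitted()
        if X is None:
            return self.em_.responsibilities_
        return e_step(X, self.model_)

    def score(self, *_args) -> float:
        """Mean Pearson correlation of in-sample landmark reconstruction."""
        self._check_fitted()
        from .tuning import profile_correlation

        result = self.predict(self.landmark_genes_)
        H = self.ref_centered_.values  # (D, K)
        rhos = [profile_correlation(result.ybar[:, i], H[i])
                for i in range(len(self.landmark_genes_))]
        return float(np.mean(rhos))
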