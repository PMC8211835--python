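"""Hyperparameter selection for the weighting kernel by cross-validation.

The kernel hyperparameters (alpha, beta) are chosen on a grid by held-out
prediction of landmark genes: each fold removes genes from the *reference*
side, refits the whole map (preprocessing, PLSC, EM) without them, predicts
their spatial profiles from the scRNA-seq data, and scores the prediction
against the withheld reference profile. Scores are Pearson correlations
aggregated into an approximate mutual information

    J(alpha, beta) = -1/2 sum_i ln(1 - rho_i(alpha, beta)^2)

(each gene's predicted/reference profile pair treated as bivariate Gaussian),
or ROC areas summed over genes when the reference is binary. Because the
refit does not depend on (alpha, beta), each fold is fitted once and all grid
points are evaluated against the cached distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .containers import ExpressionMatrix, SpatialReference
from .pipeline import SpatialGeneMapper
from .plsc import ParameterError
from .reconstruct import WeightConfig, compute_weights, reconstruct_expression

DEFAULT_GRID = [(a, b)
                for a in (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0)
                for b in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]


@dataclass
class CVResult:
    """Grid-search outcome: objective per grid point, the winner, per-gene scores."""

    grid: list[tuple[float, float]]
    objective: list[float]
    best: WeightConfig
    per_gene_scores: dict[str, float]
    objective_name: str = "mi"
    on_boundary: bool = False
    score_table: dict = field(default_factory=dict, repr=False)


def profile_correlation(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pearson correlation between a predicted and a reference spatial profile."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ParameterError("profiles must be 1-D vectors of equal length")
    if pred.size < 3:
        raise ParameterError("need at least 3 positions for a correlation")
    if pred.std() == 0.0 or ref.std() == 0.0:
        warnings.warn("zero-variance profile; correlation undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(pred, ref)[0, 1])


def mutual_information_objective(rhos: np.ndarray, clip: float = 0.999) -> float:
    """Approximate mutual information J = -1/2 sum ln(1 - rho^2).

    Correlations are clipped at ``clip`` in magnitude so a perfect correlation
    contributes a large finite term instead of diverging. NaN entries
    (unscoreable genes) are ignored.
    """
    rhos = np.asarray(rhos, dtype=float)
    if not (0.0 < clip < 1.0):
        raise ParameterError("clip must lie in (0, 1)")
    r2 = np.minimum(rhos[np.isfinite(rhos)] ** 2, clip**2)
    return float(-0.5 * np.sum(np.log1p(-r2)))


def roc_objective(pred: np.ndarray, ref_binary: np.ndarray) -> float:
    """Area under the ROC curve of ``pred`` as a score for ``ref_binary`` = 1.

    Computed from the Mann-Whitney rank statistic; ties get midranks, i.e.
    each tied positive/negative pair contributes 1/2.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref_binary)
    labels = np.unique(ref)
    if not np.isin(labels, (0, 1)).all():
        raise ParameterError("reference must be binary (0/1)")
    n_pos = int(np.sum(ref == 1))
    n_neg = int(np.sum(ref == 0))
    if n_pos == 0 or n_neg == 0:
        warnings.warn("one-class reference profile; ROC undefined", stacklevel=2)
        return float("nan")
    ranks = rankdata(pred)
    u = ranks[ref == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _make_folds(genes: list[str], cv_mode: str, n_folds: int,
                seed: int) -> list[list[str]]:
    if cv_mode == "loo":
        return [[g] for g in genes]
    if cv_mode != "kfold":
        raise ParameterError(f"unknown cv_mode {cv_mode!r}")
    if not (2 <= n_folds <= len(genes)):
        raise ParameterError("n_folds must be in [2, n_genes]")
    rng = np.random.default_rng(seed)
    order = list(np.array(genes)[rng.permutation(len(genes))])
    folds = [order[i::n_folds] for i in range(n_folds)]
    return [sorted(f) for f in folds]


def _fold_targets(ref: SpatialReference, genes: list[str], objective: str,
                  mapper: SpatialGeneMapper) -> np.ndarray:
    """Reference profiles the held-out predictions are scored against."""
    full = ref.expr.subset_genes(genes).values
    if objective == "roc":
        return full  # raw binary labels
    if mapper.log_transform_ref:
        full = np.log(full + mapper.pseudo)
    return full - full.mean(axis=1, keepdims=True)


def _scan(sc: ExpressionMatrix, ref: SpatialReference,
          grid: list[tuple[float, float]], folds: list[list[str]],
          objective: str, mapper_params: dict | None) -> tuple[list[str], np.ndarray]:
    """Held-out score of every scoreable gene at every grid point.

    Returns (gene order, score matrix genes x grid points). Each fold is
    refitted once; all grid points reuse its cached distances.
    """
    params = dict(mapper_params or {})
    configs = [WeightConfig(a, b) for a, b in grid]
    gene_order: list[str] = []
    rows: list[np.ndarray] = []
    for fold in folds:
        kept = [g for g in ref.expr.gene_ids if g not in set(fold)]
        if len(kept) < 2:
            raise ParameterError("fold removal leaves fewer than 2 landmarks")
        mapper = SpatialGeneMapper(**params).fit(sc, ref.subset_genes(kept))
        from .reconstruct import mahalanobis_distances

        D = mahalanobis_distances(mapper.X_, mapper.model_.mu,
                                  mapper.model_.sigma2)
        scoreable = [g for g in fold if g in set(mapper.sc_centered_.gene_ids)]
        if not scoreable:
            continue
        payload = mapper.sc_centered_.subset_genes(scoreable).values
        targets = _fold_targets(ref, scoreable, objective, mapper)
        fold_scores = np.empty((len(scoreable), len(configs)))
        for ci, cfg in enumerate(configs):
            w = compute_weights(D, mapper.model_.pi, cfg)
            pred = reconstruct_expression(payload, w)  # (K, G_f)
            for gi in range(len(scoreable)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if objective == "roc":
                        fold_scores[gi, ci] = roc_objective(pred[:, gi],
                                                            targets[gi])
                    else:
                        rho = profile_correlation(pred[:, gi], targets[gi])
                        fold_scores[gi, ci] = rho
        gene_order.extend(scoreable)
        rows.append(fold_scores)
    if not rows:
        raise ParameterError("no scoreable genes in any fold")
    return gene_order, np.vstack(rows)


def _objective_values(scores: np.ndarray, objective: str,
                      clip: float) -> np.ndarray:
    if objective == "roc":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.nansum(scores, axis=0)
    return np.array([mutual_information_objective(scores[:, c], clip)
                     for c in range(scores.shape[1])])


def _pick_best(grid: list[tuple[float, float]],
               values: np.ndarray) -> tuple[int, bool]:
    finite = np.isfinite(values)
    if not finite.any():
        raise ParameterError("every grid point produced an unusable objective")
    best_val = values[finite].max()
    # deterministic, grid-order-invariant tie-break: smallest (alpha, beta)
    candidates = [i for i in range(len(grid))
                  if finite[i] and values[i] == best_val]
    best = min(candidates, key=lambda i: grid[i])
    alphas = [a for a, _ in grid]
    betas = [b for _, b in grid]
    on_boundary = (grid[best][0] == max(alphas) and len(set(alphas)) > 1) or (
        grid[best][1] == max(betas) and len(set(betas)) > 1)
    return best, on_boundary


def loo_predict_gene(sc: ExpressionMatrix, ref: SpatialReference, gene: str,
                     config: WeightConfig,
                     mapper_params: dict | None = None) -> np.ndarray:
    """Predict one landmark's spatial profile with that gene held out.

    The gene is removed from the reference before PLSC and EM (full refit, so
    nothing leaks through the metagene space); its profile is then
    reconstructed from the complete scRNA-seq matrix.
    """
    if gene not in ref.expr.gene_ids:
        raise KeyError(f"gene {gene!r} is not a reference landmark")
    kept = [g for g in ref.expr.gene_ids if g != gene]
    if len(kept) < 2:
        raise ParameterError("holding out this gene leaves < 2 landmarks")
    params = dict(mapper_params or {})
    mapper = SpatialGeneMapper(**params).fit(sc, ref.subset_genes(kept))
    result = mapper.predict([gene], alpha=config.alpha, beta=config.beta)
    return result.ybar[:, 0]


def grid_search(sc: ExpressionMatrix, ref: SpatialReference,
                grid: list[tuple[float, float]] | None = None,
                cv_mode: str = "loo", objective: str = "mi", seed: int = 0,
                n_folds: int = 10, clip: float = 0.999,
                mapper_params: dict | None = None) -> CVResult:
    """Choose (alpha, beta) maximizing the cross-validated objective.

    ``cv_mode`` "loo" holds out one landmark per fold; "kfold" partitions the
    landmarks into ``n_folds`` groups by a seeded shuffle. ``objective`` "mi"
    aggregates Pearson correlations into J; "roc" sums ROC areas (binary
    references). Deterministic given ``seed``.
    """
    if grid is None:
        grid = list(DEFAULT_GRID)
    grid = [(float(a), float(b)) for a, b in grid]
    if not grid:
        raise ParameterError("empty hyperparameter grid")
    if objective not in ("mi", "roc"):
        raise ParameterError(f"unknown objective {objective!r}")
    folds = _make_folds(list(ref.expr.gene_ids), cv_mode, n_folds, seed)
    genes, scores = _scan(sc, ref, grid, folds, objective, mapper_params)
    values = _objective_values(scores, objective, clip)
    best_idx, on_boundary = _pick_best(grid, values)
    if on_boundary:
        warnings.warn("objective maximized on the grid boundary; consider "
                      "extending the grid range", stacklevel=2)
    per_gene = {g: float(scores[i, best_idx]) for i, g in enumerate(genes)}
    return CVResult(
        grid=grid, objective=[float(v) for v in values],
        best=WeightConfig(*grid[best_idx]), per_gene_scores=per_gene,
        objective_name=objective, on_boundary=on_boundary,
        score_table={"genes": genes, "scores": scores},
    )


def evaluate_prediction(sc: ExpressionMatrix, ref: SpatialReference,
                        best: WeightConfig, mode: str = "reconstruction",
                        grid: list[tuple[float, float]] | None = None,
                        objective: str = "mi", seed: int = 0,
                        clip: float = 0.999,
                        mapper_params: dict | None = None) -> dict[str, float]:
    """Per-gene prediction scores.

    ``reconstruction`` scores the in-sample reconstruction of every landmark
    at ``best``. ``loocv_refit`` is the unbiased protocol: for each gene, the
    hyperparameters are re-optimized on the remaining genes' held-out
    objective before scoring the held-out gene.
    """
    params = dict(mapper_params or {})
    if mode == "reconstruction":
        mapper = SpatialGeneMapper(**params).fit(sc, ref)
        result = mapper.predict(mapper.landmark_genes_, alpha=best.alpha,
                                beta=best.beta)
        targets = _fold_targets(ref, mapper.landmark_genes_, objective, mapper)
        out: dict[str, float] = {}
        for i, g in enumerate(mapper.landmark_genes_):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if objective == "roc":
                    out[g] = roc_objective(result.ybar[:, i], targets[i])
                else:
                    out[g] = profile_correlation(result.ybar[:, i], targets[i])
        return out
    if mode != "loocv_refit":
        raise ParameterError(f"unknown mode {mode!r}")
    if grid is None:
        grid = list(DEFAULT_GRID)
    folds = _make_folds(list(ref.expr.gene_ids), "loo", 0, seed)
    genes, scores = _scan(sc, ref, grid, folds, objective, mapper_params)
    out = {}
    for i, g in enumerate(genes):
        others = np.delete(scores, i, axis=0)
        values = _objective_values(others, objective, clip)
        best_idx, _ = _pick_best(grid, values)
        out[g] = float(scores[i, best_idx])
    return out
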