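"""Ground-truth tissue and scRNA-seq simulator.

The generator mirrors the package's own generative assumptions so that every
stage is testable without external atlases: a tissue is a set of K positions
on a grid carrying smooth landmark patterns (stripes, gradients, or Gaussian
spots); each simulated cell draws an origin position z ~ Categorical(pi) and
expresses landmark gene i as

    x_i = a_i * h_{z,i} + b_i + c_i * xi,   xi ~ N(0, 1)

(the affine map applied directly in gene space, so the generating (a, b, c)
are an unambiguous recovery target). Non-landmark genes are fixed random
linear combinations of the landmark patterns plus matched noise. All
randomness flows through one ``numpy.random.default_rng`` (PCG64) seed, so a
seed reproduces every field bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import ExpressionMatrix, SpatialReference
from .em import MappingModel, e_step, map_reference
from .plsc import MetageneSpace, ParameterError
from .reconstruct import WeightConfig, compute_weights, mahalanobis_distances
from .tuning import profile_correlation

PATTERN_FAMILIES = ("stripes", "gradients", "spots", "mixed")


@dataclass
class SyntheticTruth:
    """A simulated dataset together with everything that generated it."""

    ref: SpatialReference
    sc: ExpressionMatrix
    true_model: MappingModel
    true_origin: np.ndarray             # (N,) position indices
    nonlandmark_loadings: np.ndarray    # (n_nonlandmark, D) over landmark patterns
    noise_draws: np.ndarray             # (D + n_nonlandmark, N) standard normals
    seed: int

    @property
    def landmark_genes(self) -> list[str]:
        return list(self.ref.expr.gene_ids)


def _grid_coords(K: int, dims: int) -> np.ndarray:
    side = int(np.ceil(K ** (1.0 / dims)))
    axes = np.meshgrid(*[np.linspace(0.0, 1.0, side)] * dims, indexing="ij")
    pts = np.stack([a.ravel() for a in axes], axis=1)
    return pts[:K]


def generate_tissue(K: int = 100, n_landmarks: int = 30,
                    pattern_family: str = "mixed", coord_dims: int = 2,
                    seed: int = 0, n_duplicate: int = 0,
                    n_zero_variance: int = 0,
                    binary: bool = False) -> SpatialReference:
    """Simulate a spatial reference atlas.

    Positions sit on a regular grid in the unit square/cube; each landmark is
    a smooth spatial function of the coordinates. ``n_duplicate`` appends
    exact copies of the first landmarks (redundancy stress), and
    ``n_zero_variance`` appends constant landmarks. With ``binary`` the
    continuous patterns are thresholded at their median into {0, 1}.
    """
    if K < 4:
        raise ParameterError("K must be >= 4")
    if n_landmarks < 2:
        raise ParameterError("n_landmarks must be >= 2")
    if pattern_family not in PATTERN_FAMILIES:
        raise ParameterError(
            f"pattern_family must be one of {PATTERN_FAMILIES}")
    rng = np.random.default_rng(seed)
    coords = _grid_coords(K, coord_dims)
    side = int(np.ceil(K ** (1.0 / coord_dims)))
    max_freq = max(1, (side - 1) // 2)  # keep stripes above the grid Nyquist rate
    H = np.empty((n_landmarks, K))
    for j in range(n_landmarks):
        if pattern_family == "mixed":
            family = ("stripes", "gradients", "spots")[j % 3]
        else:
            family = pattern_family
        if family == "stripes":
            axis = j % coord_dims
            freq = 1 + (j // coord_dims) % max_freq
            phase = rng.uniform(0.0, 2.0 * np.pi)
            H[j] = np.sin(2.0 * np.pi * freq * coords[:, axis] + phase)
        elif family == "gradients":
            if j < coord_dims:
                direction = np.zeros(coord_dims)
                direction[j] = 1.0  # first landmarks: one per coordinate axis
            else:
                direction = rng.normal(size=coord_dims)
                direction /= np.linalg.norm(direction)
            H[j] = coords @ direction
        else:  # spots
            center = rng.uniform(0.0, 1.0, size=coord_dims)
            width = rng.uniform(0.15, 0.4)
            d2 = np.sum((coords - center) ** 2, axis=1)
            H[j] = np.exp(-d2 / (2.0 * width**2))
    if n_duplicate:
        H = np.vstack([H, H[:n_duplicate]])
    if n_zero_variance:
        H = np.vstack([H, np.zeros((n_zero_variance, K))])
    if binary:
        med = np.median(H, axis=1, keepdims=True)
        H = (H > med).astype(float)
    else:
        H = H - H.mean(axis=1, keepdims=True)
    names = [f"lm{j:03d}" for j in range(n_landmarks)]
    names += [f"lm{j:03d}_dup" for j in range(n_duplicate)]
    names += [f"lm_const{j:03d}" for j in range(n_zero_variance)]
    expr = ExpressionMatrix(H, names, [f"pos{k:04d}" for k in range(K)])
    return SpatialReference(expr, coords, None, is_binary=binary)


def generate_cells(ref: SpatialReference, N: int = 2000,
                   true_a: np.ndarray | None = None,
                   true_b: np.ndarray | None = None,
                   true_c: float | np.ndarray = 0.3,
                   pi: np.ndarray | None = None, n_nonlandmark: int = 0,
                   seed: int = 0) -> SyntheticTruth:
    """Simulate scRNA-seq cells from a reference tissue.

    Defaults: sensitivities a ~ U(0.5, 2), backgrounds |b| ~ U(0.5, 1.5) with
    random sign (kept away from 0 so relative errors are well-posed), uniform
    origin probabilities, and a scalar ``true_c`` interpreted as a fraction of
    each gene's signal standard deviation (an array is taken as absolute noise
    scales). The returned matrix is the raw model draw, uncentered.
    """
    rng = np.random.default_rng(seed)
    H = ref.expr.values
    D, K = H.shape
    if true_a is None:
        true_a = rng.uniform(0.5, 2.0, size=D)
    true_a = np.asarray(true_a, dtype=float)
    if true_b is None:
        true_b = rng.uniform(0.5, 1.5, size=D) * rng.choice([-1.0, 1.0], size=D)
    true_b = np.asarray(true_b, dtype=float)
    if pi is None:
        pi = np.full(K, 1.0 / K)
    pi = np.asarray(pi, dtype=float)
    if true_a.shape != (D,) or true_b.shape != (D,):
        raise ParameterError("true_a/true_b must have one entry per landmark")
    if pi.shape != (K,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ParameterError("pi must be a probability vector over positions")
    signal_sd = np.maximum((true_a[:, None] * H).std(axis=1), 1e-12)
    if np.isscalar(true_c) or np.asarray(true_c).ndim == 0:
        if float(true_c) < 0:
            raise ParameterError("true_c must be nonnegative")
        c = float(true_c) * signal_sd
    else:
        c = np.asarray(true_c, dtype=float)
        if c.shape != (D,) or np.any(c < 0):
            raise ParameterError("true_c must be nonnegative, one per landmark")

    origin = rng.choice(K, size=N, p=pi)
    xi = rng.standard_normal((D + n_nonlandmark, N))
    landmark_block = (true_a[:, None] * H[:, origin] + true_b[:, None]
                      + c[:, None] * xi[:D])

    loadings = np.zeros((n_nonlandmark, D))
    if n_nonlandmark:
        loadings = rng.normal(scale=1.0 / np.sqrt(D), size=(n_nonlandmark, D))
        patterns = loadings @ H                       # (n_nonlandmark, K)
        nl_sd = np.maximum(patterns.std(axis=1), 1e-12)
        frac = float(true_c) if np.isscalar(true_c) else float(np.mean(
            c / signal_sd))
        nl_block = patterns[:, origin] + (frac * nl_sd)[:, None] * xi[D:]
        values = np.vstack([landmark_block, nl_block])
    else:
        values = landmark_block
    genes = list(ref.expr.gene_ids) + [f"nl{g:04d}" for g in range(n_nonlandmark)]
    sc = ExpressionMatrix(values, genes, [f"cell{n:05d}" for n in range(N)])
    sigma2 = np.maximum(c**2, np.finfo(float).tiny)
    model = MappingModel(pi, true_a, true_b, sigma2,
                         np.empty((D, K)), "fixed_uniform")
    model.mu = map_reference(model, H)
    return SyntheticTruth(ref=ref, sc=sc, true_model=model, true_origin=origin,
                          nonlandmark_loadings=loadings, noise_draws=xi,
                          seed=int(seed))


@dataclass
class RecoveryReport:
    """Fit-vs-truth comparison on a synthetic dataset."""

    rel_err_a: float
    rel_err_b: float
    rel_err_sigma2: float
    origin_accuracy: float
    chance_accuracy: float
    reconstruction_corr: float
    n_ambiguous_positions: int

    def to_dict(self) -> dict:
        return {k: (int(v) if isinstance(v, (int, np.integer)) else float(v))
                for k, v in self.__dict__.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RecoveryReport":
        return cls(**json.loads(text))


def recovery_report(truth: SyntheticTruth, fitted: MappingModel,
                    metagene_space: MetageneSpace | None = None,
                    X: np.ndarray | None = None) -> RecoveryReport:
    """Compare a fitted model against the generating truth.

    With a gene-space fit (``metagene_space=None``) the fitted (a, b, sigma2)
    are compared entry-wise with the generating parameters (median relative
    error). Under a PLSC fit the raw parameters live in metagene coordinates
    and are not directly comparable, so only the mapped means' reconstruction
    and origin accuracy are meaningful there. ``X`` is the matrix the model
    was fitted on (defaults to the raw landmark block).
    """
    D = truth.ref.expr.n_genes
    if X is None:
        X = truth.sc.values[:D]
    if fitted.n_metagenes != X.shape[0]:
        raise ParameterError("fitted model does not match the given X")
    truth_m = truth.true_model
    if metagene_space is None:
        if fitted.n_metagenes != D:
            raise ParameterError("gene-space comparison needs one metagene "
                                 "per landmark")
        rel_a = np.median(np.abs(fitted.a - truth_m.a) / np.abs(truth_m.a))
        rel_b = np.median(np.abs(fitted.b - truth_m.b) / np.abs(truth_m.b))
        safe = np.maximum(truth_m.sigma2, np.finfo(float).tiny)
        rel_s = np.median(np.abs(fitted.sigma2 - truth_m.sigma2) / safe)
    else:
        rel_a = rel_b = rel_s = float("nan")
    posterior = e_step(X, fitted)
    mode = posterior.argmax(axis=1)
    accuracy = float(np.mean(mode == truth.true_origin))
    # positions indistinguishable by their landmark signature
    H = truth.ref.expr.values
    sig = (truth_m.a[:, None] * H + truth_m.b[:, None]).T
    _, inverse, counts = np.unique(np.round(sig, 9), axis=0,
                                   return_inverse=True, return_counts=True)
    ambiguous = int(np.sum(counts[inverse] > 1))
    # posterior-weighted reconstruction of the landmark patterns
    Dnk = mahalanobis_distances(X, fitted.mu, fitted.sigma2)
    w = compute_weights(Dnk, fitted.pi, WeightConfig(0.5, 0.0))
    col = w.sum(axis=0)
    ybar = (w.T @ X.T) / np.maximum(col, np.finfo(float).tiny)[:, None]
    corrs = [profile_correlation(ybar[:, i], H[i])
             for i in range(D) if H[i].std() > 0]
    return RecoveryReport(
        rel_err_a=float(rel_a), rel_err_b=float(rel_b),
        rel_err_sigma2=float(rel_s), origin_accuracy=accuracy,
        chance_accuracy=1.0 / truth.ref.n_positions,
        reconstruction_corr=float(np.mean(corrs)),
        n_ambiguous_positions=ambiguous,
    )


def save_truth(truth: SyntheticTruth, directory: str | Path) -> None:
    """Write ref matrix, coordinates, sc matrix, and the truth archive."""
    from . import io as gio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gio.write_expression_matrix(truth.ref.expr, directory / "reference.tsv")
    gio.write_coordinates(truth.ref, directory / "coordinates.tsv")
    gio.write_expression_matrix(truth.sc, directory / "scrnaseq.tsv")
    gio.save_archive(
        directory / "truth.npz",
        {**{f"model_{k}": v for k, v in truth.true_model.arrays().items()},
         "true_origin": truth.true_origin,
         "nonlandmark_loadings": truth.nonlandmark_loadings,
         "noise_draws": truth.noise_draws},
        {"seed": truth.seed, "is_binary": truth.ref.is_binary},
    )
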