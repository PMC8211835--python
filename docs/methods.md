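# Methods

## Model

Let `h_k ∈ R^D` be the landmark expression of tissue position k (K positions,
coordinates known) and `y_n ∈ R^{D'}` the genome-wide expression of
dissociated cell n (N cells, positions unknown). Both matrices are
gene-centered (optionally after `log(x + pseudo)`), aligned on the D shared
landmark genes, and reduced to M metagenes by partial least squares
correlation: `W = YᵀH` (N×K) is factorized `W ≈ Uᵀ Δ V` by truncated SVD and
the metagene coordinates are `x_n = Δ u_n`, `r_k = Δ v_k`. Reduction removes
landmark redundancy (spatially correlated landmark clusters collapse into
single factors), which otherwise biases the mapping fit.

Cells are modeled as draws from a K-component Gaussian mixture in metagene
space,

```
p(x | θ) = Σ_k π_k N(x | A r_k + b, Σ),   A = diag(a), Σ = diag(σ²), σ_j = c_j
```

so each cell is a noisy affine image of some reference position. `a_j`
absorbs platform sensitivity differences, `b_j` background, `c_j` per-factor
noise intensity. The shared diagonal covariance keeps every M-step update
closed-form.

**EM.** E-step: responsibilities `γ_nk ∝ π_k N(x_n | μ_k, Σ)` (log-space,
log-sum-exp). M-step, per metagene i, with weighted sums
`φ_i = Σ_{nk} γ_nk x_ni`, `χ_i = Σ_{nk} γ_nk r_ki`,
`ψ_i = Σ_{nk} γ_nk x_ni r_ki`, `ω_i = Σ_{nk} γ_nk r_ki²`:

```
b_i = (ω_i φ_i − ψ_i χ_i) / (N ω_i − χ_i²)
a_i = (ψ_i − χ_i b_i) / ω_i
σ_i² = (1/N) Σ_{nk} γ_nk (x_ni − a_i r_ki − b_i)²
```

(b before a, then σ², following the update dependency). With one-hot
responsibilities this is exactly per-metagene ordinary least squares of x on
r, which is how the update is verified in the tests. π is updated as
`π_k = Σ_n γ_nk / N` only in `updated` mode; the default holds π fixed —
uniform, or proportional to supplied position masses (e.g. liver-zone areas)
— which matches tissues divided into equal subregions and converges faster.
Initialization is moment matching: `a_i = sd(x_i)/sd(r_i)`,
`b_i = mean(x_i) − a_i mean(r_i)`, `σ_i² = var(x_i)` (population moments).

**Reconstruction.** Position k's expression of any gene set is the weighted
mean of all cells, `ȳ_k = Σ_n w_nk y_n / Σ_j w_jk`, with
`w_nk ∝ π_k exp(−α D²_nk − β D_nk)` and `D_nk` the Mahalanobis distance
under the fitted Σ. Weights depend only on the metagene space, so one weight
matrix serves all ~10,000 genes. At `(α, β) = (1/2, 0)` the weights equal the
mixture posterior exactly (the Gaussian normalizer cancels because Σ is
shared); the package asserts this identity across modules at 1e−10.

**Tuning.** `(α, β)` are selected on a grid by leave-one-gene-out CV: each
fold removes a landmark from the *reference* and refits preprocessing, PLSC
and EM without it (a full refit — removing the gene only from scoring would
leak it through the metagene space; a faster weights-only approximation
exists behind a flag, off by default). Held-out profiles are scored by
Pearson correlation and aggregated into `J = −½ Σ_i ln(1 − ρ_i²)`, the
mutual information of a per-gene bivariate Gaussian (verified against 2-D
quadrature); `ρ` is clipped at 0.999 since J diverges at |ρ| = 1. Binary
atlases are scored by ROC area (midrank ties) summed over genes. Because the
fold refits do not depend on (α, β), each fold is fitted once and every grid
point reuses its cached distances; the per-gene re-optimization protocol
(`loocv_refit`) then costs nothing extra. The best grid point is chosen with
a deterministic, grid-order-invariant tie-break (smallest (α, β)); a maximum
on the grid boundary triggers a warning to extend the grid.

**Origin prediction.** A cell's origin posterior is the responsibility at
the fitted model. Specificity is quantified on the union-symmetrized,
unweighted k-NN graph (default k = 6) of the position coordinates: the mean
hop distance from the best position to the next `top_m = 3` posterior ranks,
and the cumulative posterior mass within each hop radius of the best
position (non-decreasing in the radius, 1 at the diameter).

## Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| pseudo-count | 1 | conventional for log-transforming counts and binary atlases (maps {0,1} to a monotone pair); configurable |
| M (metagenes) | min(60, min(D, N, K) − 1) | 60 suits a BDTNP-sized panel (84 landmarks); the cap guards small inputs |
| π mode | fixed_uniform | equal-area tissue subdivisions; `fixed_mass` for unequal zones; `updated` optional |
| EM tolerance / max_iter | 1e−6 relative / 1000 | no stated convention; the fit typically converges in < 10 iterations |
| σ² floor | 1e−8 × var(x_i) | prevents singular components on noise-free or duplicated data |
| (α, β) grid | α ∈ {0, .05, .1, .25, .5, 1, 2, 4}, β ∈ {0, .5, 1, 2, 4, 8} | spans sub-posterior to sharp weighting; boundary warning prompts extension |
| k-NN k / top_m | 6 / 3 | standard specificity convention for single-cell-resolution atlases |

## Synthetic data

`generate_tissue` places K positions on a regular grid in the unit
square/cube and draws landmarks from three smooth families — sinusoidal
stripes along an axis (frequency capped at the grid Nyquist rate), linear
gradients (the first `coord_dims` axis-aligned, the rest random), Gaussian
spots — centered per gene. Degenerate options add duplicated landmarks,
constant landmarks, or a median-thresholded binary atlas. `generate_cells`
draws each cell's origin from π and applies the affine map *in gene space*
(metagene = gene identity), so the generating (a, b, c) are an unambiguous
recovery target; non-landmark genes are random linear combinations of the
landmark patterns plus matched noise. Study-condition defaults: K = 100,
30 landmarks, N = 2000, noise c = 0.3 × per-gene signal sd, a ~ U(0.5, 2),
|b| ~ U(0.5, 1.5) with random sign (bounded away from 0 so relative errors
on b are well-posed), π uniform. All draws come from one
`numpy.random.default_rng` (PCG64) seed and regenerate bit-identically.

What the simulator does *not* emulate: count-level noise (dropout, negative
binomial overdispersion), batch effects, or genes whose spatial pattern
differs between modalities. Passing tests therefore demonstrate correctness
of the algorithm under its own model assumptions — well-specified affine
mapping with Gaussian noise — not robustness to the full messiness of real
scRNA-seq/ISH pairs, where accuracy is bounded by model misfit.

## Numerical choices

- All mixture arithmetic in log space; distances via the scaled
  inner-product expansion clamped at 0.
- SVD signs fixed so each right-singular row's largest-|·| entry is positive
  (reproducibility); near-tied singular values trigger a warning since the
  factor order within tied blocks is arbitrary.
- M may exceed the gene dimension's numerical rank (it is bounded by
  min(N, K)); deficiency warns and the EM holds degenerate metagenes at
  their previous (a, b) values when `N ω_i − χ_i²` is singular.
- Exact distance ties under sharp α share weight equally (softmax behavior).
- A position receiving zero total weight falls back to the global cell mean,
  flagged.
- A zero-variance profile scores correlation 0 (flagged); a one-class binary
  profile is excluded from the ROC objective.
- The weight-sensitivity diagnostic `dw_nk/dx_ni =
  w(1−w)(−2αD−β)/D · (x−μ)/σ²` keeps only the k-th term of the softmax
  Jacobian (competing positions' distances treated as stationary); it is
  exact when the probed coordinate matches the competitors' means and is
  validated against finite differences there. `D_nk = 0` returns NaN.
- EM itself is deterministic (single moment-matched start); seeds govern
  only data generation and fold shuffling, and every artifact re-fits
  byte-identically.

## Design notes

- The package is organized as scikit-learn-style estimators (`PLSC`,
  `GenerativeMapEM`, `SpatialGeneMapper`: `fit` / `predict` /
  `get_params`, fitted attributes with trailing underscores) because the
  method is fit/predict-shaped; module-level functions remain thin wrappers.
- Gene matching is exact, case-sensitive string equality with an opt-in
  case-insensitive switch.
- Zero-variance gene rows survive centering but are excluded before PLSC
  (they would contribute zero rows to the cross-product while risking
  degenerate correlations downstream); exclusions are reported.
- Reconstructions are returned on the centered (log) scale; an explicit
  inverse transform (add gene means back, `expm1` if a log was applied) is
  available, since reported scales are a presentation choice.
- How many metagenes to keep is genuinely open (a manual choice in
  practice); `choose_m` offers fixed, variance-fraction and elbow criteria
  but no criterion claims to reproduce a manual extraction.

## Limitations

- Shared diagonal covariance: no gene-gene noise correlations, no
  per-position covariances.
- The affine map is global; modality differences that vary across the
  tissue are not modeled.
- LOO tuning refits the pipeline once per landmark; for atlases with
  ~1000 landmarks use `cv_mode="kfold"` (ten folds is the provided
  convention).
- Problem sizes in the test-suite and acceptance runs (N ≤ 2000, K ≤ 200)
  were chosen as the smallest at which recovery statistics stabilize;
  results at those sizes are reported as medians over seeds.
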