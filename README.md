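# glimap

Spatial reconstruction of genome-wide gene expression from dissociated
scRNA-seq data, using an in situ hybridization (ISH) atlas of landmark genes
as the spatial reference.

scRNA-seq measures ~10,000 genes per cell but destroys the cells' positions;
ISH atlases record where a small panel of landmark genes is expressed, at
known tissue coordinates. `glimap` links the two modalities with a
*generative linear model*: the expression of landmark gene *i* observed by
scRNA-seq is modeled as an affine, noisy image of its ISH measurement,

```
y_i = a_i h_i + b_i + c_i ξ_i ,      ξ_i ~ N(0, 1)
```

where `a_i` is a sensitivity (scale) difference between the platforms, `b_i`
a background offset, and `c_i` a gene-specific noise intensity. Every
parameter has a measurement-process interpretation — this is what
distinguishes the approach from model-free nearest-neighbor integration.

## Method

1. **Preprocessing** — both matrices are optionally `log(x + pseudo)`
   transformed and gene-centered, then aligned on shared landmark genes.
2. **Metagene reduction (PLSC)** — partial least squares correlation: the
   cross-product `W = YᵀH` of the centered datasets is factorized by
   truncated SVD; scaling the singular vectors by the singular values yields
   M "metagene" coordinates `x_n` (cells) and `r_k` (positions) that capture
   correlated landmark clusters and remove redundancy.
3. **EM fit** — cells are modeled by a K-component Gaussian mixture whose
   component means are the affine-mapped reference positions
   `μ_k = A r_k + b` with shared diagonal covariance `Σ = diag(c²)`. All
   updates are closed-form; mixture weights π can be fixed (uniform, or
   proportional to position masses such as zone areas) or re-estimated.
4. **Reconstruction** — the expression of *any* gene at position k is the
   weighted mean of all cells, with Mahalanobis-distance weights
   `w_nk ∝ π_k exp(−α D²_nk − β D_nk)`; at `(α, β) = (1/2, 0)` the weights
   are exactly the mixture posterior. Noisy metagenes contribute little to
   `D_nk`, making the reconstruction noise-resistant.
5. **Hyperparameter tuning** — `(α, β)` are chosen by leave-one-gene-out (or
   k-fold) cross-validation, maximizing the approximate mutual information
   `J = −½ Σ_i ln(1 − ρ_i²)` between held-out predictions and their reference
   profiles (or summed ROC areas when the atlas is binary).
6. **Origin prediction** — each cell's posterior over positions, with
   specificity diagnostics on the k-NN graph of tissue coordinates (mean
   path length to runner-up positions; cumulative posterior within a graph
   radius).

A bundled simulator (`glimap.synthetic`) generates ground-truth tissues
(stripe / gradient / spot patterns on a grid) and cells drawn from the model
above, so the whole pipeline is testable without external atlases.

## Worked example

```python
import numpy as np
from glimap import SpatialGeneMapper, generate_tissue, generate_cells, grid_search

ref = generate_tissue(K=100, n_landmarks=30, pattern_family="mixed", seed=0)
truth = generate_cells(ref, N=2000, true_c=0.3, n_nonlandmark=50, seed=1)

mapper = SpatialGeneMapper(n_metagenes=20).fit(truth.sc, truth.ref)
print("EM iterations:", mapper.trace_.n_iter)
print("mean landmark reconstruction r: %.3f" % mapper.score())

cv = grid_search(truth.sc, truth.ref,
                 grid=[(a, 0.0) for a in (0.1, 0.25, 0.5, 1.0, 2.0)],
                 cv_mode="loo", objective="mi", seed=0,
                 mapper_params={"n_metagenes": 20})
print("best (alpha, beta):", (cv.best.alpha, cv.best.beta))
print("mean held-out landmark r: %.3f" % np.mean(list(cv.per_gene_scores.values())))

result = mapper.predict(["nl0007"], alpha=cv.best.alpha, beta=cv.best.beta)
print("nl0007 profile over first 5 positions:", np.round(result.ybar[:5, 0], 3))
```

prints

```
EM iterations: 4
mean landmark reconstruction r: 0.998
best (alpha, beta): (2.0, 0.0)
mean held-out landmark r: 0.998
nl0007 profile over first 5 positions: [-0.053  0.51   0.638  0.734  0.408]
```

The fit converges in a few EM iterations; in-sample reconstruction and
held-out (leave-one-gene-out) prediction of landmark profiles both correlate
near-perfectly with the generating patterns at this noise level, and the
chosen α sits on the sharp side of the posterior value 1/2 (the run also
warns that the best point lies on the grid boundary — a cue to widen the
grid). `result.ybar` is the positions × genes reconstruction on the centered
log scale; `nl0007` is a simulated non-landmark gene, i.e. a gene absent from
the reference that the model can nevertheless place in space.

The same pipeline is scriptable from the shell:

```
glimap simulate --n-positions 100 --n-landmarks 30 --n-cells 2000 --outdir data
glimap fit --sc data/scrnaseq.tsv --ref data/reference.tsv --coords data/coordinates.tsv --outdir run
glimap tune --sc data/scrnaseq.tsv --ref data/reference.tsv --coords data/coordinates.tsv --outdir run
glimap reconstruct --sc data/scrnaseq.tsv --coords data/coordinates.tsv --model-dir run --genes all --outdir run
glimap predict-origin --coords data/coordinates.tsv --model-dir run --outdir run
```

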