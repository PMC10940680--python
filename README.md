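# ladist

Label-aware Mahalanobis distance for longitudinal single-cell data.

## The problem

Multi-sample single-cell RNA-seq experiments confound biology with batch
effects: every sample (mouse, patient, sequencing run) adds its own technical
shift, so Euclidean distances between cells mix real differences with
processing artifacts. In *longitudinal* designs — samples collected along a
time course or at ordered spatial positions — there is extra structure to
exploit: biological differences grow with the label distance between samples,
while batch effects do not. Differences between label-adjacent samples are
therefore mostly batch effect.

`ladist` is for analysts of developmental, disease-progression, or other
ordered multi-sample single-cell datasets who want a cell-to-cell distance
that discounts batch directions without mutating the expression values.

## The method

For cell profiles x_i (typically the first k principal components), batch
assignments C_i, and per-batch label vectors t_b (a day, or a vector like
[week, location]), the package builds the scatter matrix

    Σ̃ = Σ_i Σ_{b ≠ C_i} W_{C_i b} (x_i − m_b)(x_i − m_b)ᵀ,
    W_{ab} = exp(−‖t_a − t_b‖² / (2 l²)),

where m_b is the mean profile of batch b and l is a locality length scale
(default 1). Cross-batch deviations between label-adjacent batches — mostly
batch effect — dominate Σ̃, so the Mahalanobis distance

    d(x_i, x_j) = sqrt((x_i − x_j)ᵀ (Σ̃ + ridge·I)⁻¹ (x_i − x_j))

suppresses batch directions while preserving trajectory structure. With all
weights equal to one the construction reduces to the Qi–Davidson
alternative-clustering metric. Distances are evaluated by whitening with the
Cholesky factor L of Σ̃ + ridge·I (solving L y = x) rather than through an
explicit inverse; cost is O(n k² + k³).

The package also ships a simulator of a bifurcating 7-cell-type
differentiation trajectory (S → A/B → A1/A2/B1/B2) sampled across 7
samples / 4 days with additive per-sample batch effects and Poisson counts,
a standard preprocessing front-end (per-cell normalization, log transform,
highly-variable-gene selection, scaling, PCA), and an integration benchmark
(silhouette, isolated-label silhouette, batch silhouette, graph connectivity,
and their arithmetic mean).

## Worked example

```python
from ladist import benchmark
from ladist.pipeline import run_lad
from ladist.preprocess import PreprocessConfig
from ladist.simulate import generate

data = generate(rng_seed=0)                      # 7 samples x 300 cells, 200 genes
run = run_lad(
    data.counts, data.cells_frame(),
    batch_col="batch", label_cols="day",
    config=PreprocessConfig(n_hvg=150, n_pcs=30),
    cell_ids=data.cell_ids,
)
print(run.results.summary())

types = run.cells["cell_type"].to_numpy()
batches = run.cells["batch"].to_numpy()
for name, emb in [("pca", run.pc_embedding), ("lad", run.lad_embedding)]:
    rep = benchmark(emb, types, batches)
    print(f"{name}: batch_silhouette={rep.batch_silhouette:.3f} aggregate={rep.aggregate:.3f}")
```

prints

```
Label-Aware Distance Results
============================================
cells:            2100
features (k):     30
batches (B):      7
label dimension:  1
length scale l:   1
ridge:            22.0185
trace(sigma~):    660554
top eigenvalues:  1.442e+05, 9.544e+04, 6.743e+04, 5.495e+04, 4.518e+04
off-diag weights: min 0.01111, max 1
============================================
pca: batch_silhouette=0.741 aggregate=0.675
lad: batch_silhouette=0.946 aggregate=0.755
```

The model summary reports the fitted scatter (its trace, leading eigenvalues,
and the automatically chosen ridge) and the batch-pair weight range — here
day-adjacent samples get weight exp(−1/2) ≈ 0.61 and replicate samples at the
same day get weight 1. The benchmark rows show the effect: batch mixing
(`batch_silhouette`, 1 = perfectly mixed) rises from 0.74 in the uncorrected
PC space to 0.95 after label-aware whitening, and the four-metric aggregate
improves with it.

The same pipeline runs from the shell:

```sh
ladist simulate --out sim --seed 1
ladist transform --matrix sim/matrix.mtx --cells sim/cells.tsv \
    --batch-col batch --time-cols day --type-col cell_type \
    --n-hvg 150 --n-pcs 30 --out run
ladist benchmark --embedding run/pca_embedding.tsv \
    --embedding run/lad_embedding.tsv \
    --cells run/cell_annotations.tsv \
    --type-col cell_type --batch-col batch --out scores
```

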