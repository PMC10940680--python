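# Methods

## Model

The label-aware distance treats batch correction as metric learning rather
than data correction. Given cell profiles x_i ∈ R^k, batch assignments C_i,
and one numeric label vector t_b per batch (collection day, disease stage, or
a combined vector such as [week, location]), the scatter matrix

    Σ̃ = Σ_i Σ_{b ≠ C_i} W_{C_i b} (x_i − m_b)(x_i − m_b)ᵀ,
    W_{ab} = exp(−‖t_a − t_b‖² / (2 l²)),

accumulates the deviations of every cell from the mean profile m_b of every
*other* batch, weighted by the squared-exponential proximity of the two
batches' labels. Distance is then the Mahalanobis form under Σ̃ + ridge·I.

Assumptions this encodes:

* **Locality.** Biological change accumulates with label distance while the
  batch effect does not, so cross-batch deviations between label-adjacent
  batches are dominated by batch effect and are the directions to shrink.
  When the assumption fails (e.g., abrupt biological change between adjacent
  time points), those biological directions are suppressed too.
* **Shared, additive batch structure.** The construction removes variance
  *directions*; it is most effective when batch effects are approximately
  additive offsets in the embedding space.
* **Replicates.** Distinct batches with identical labels get weight exactly
  1 against each other, so pure replicate batch effect is fully counted.
  This falls out of the weight formula; no special-casing.
* **Degenerate case.** With one batch the double sum is empty, Σ̃ = 0, and
  (after the ridge) the metric is a uniform rescaling of Euclidean distance.
  This is a warning, not an error, so pipelines still run.
* With all weights pinned at 1 (length scale → ∞) the scatter coincides with
  the Qi–Davidson alternative-clustering construction; tests pin this
  equivalence against a brute-force double loop.

## Numerical evaluation

Σ̃ can be singular (single batch, k above the effective rank), so a ridge is
added before factorization. Default: `1e-3 · trace(Σ̃)/k`, with an absolute
floor of `1e-8` when the trace is zero. A trace-relative ridge keeps the
factorization well-posed at every data scale without distorting dominant
directions; pass `ridge=` explicitly to override. If the factorization still
fails, the error says to raise the ridge.

All distances go through the lower Cholesky factor L of Σ̃ + ridge·I: rows
are whitened by the triangular solve L y = x, after which Euclidean geometry
equals the label-aware geometry. No explicit inverse is ever formed outside
the test oracles. Grouping the scatter sum by batch pair evaluates Σ̃ in
O(n k² + B² k²), and the whitening in O(n k²); weights are computed once per
batch pair (W depends on cells only through their batch), which is
mathematically identical to the per-cell definition at O(B² d) cost.

Σ̃ is not normalized by the number or total weight of its terms: any global
rescaling of Σ̃ rescales all distances uniformly, which distance-based
downstream steps ignore. The metric is self-normalizing under data rescaling
(x → cx with ridge → c²·ridge leaves all distances unchanged); a test checks
this exactly.

The pipeline applies the metric in PC space with k = 30 by default; the core
is space-agnostic and accepts any numeric matrix. Whether to fit on scaled
expression or PC coordinates was genuinely open; PC space matches the stated
O(nk² + k³) complexity contract and standard practice, and is the default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `length_scale` (l) | 1 | label distance at which batch pairs count as close; weight exp(−1/2) at Δ = l. In day/week units. Sensitivity is generally mild; search if labels are on unusual scales. |
| `ridge` | trace-relative (see above) | diagonal loading of Σ̃, in squared profile units |
| `n_hvg` | 2000 (150 in simulation studies) | highly variable genes kept |
| `n_pcs` | 30 | PCA dimensionality, the k of the complexity contract |
| `k_neighbors` | 15 | kNN graph size for graph connectivity |

## Preprocessing conventions

Per-cell normalization scales each cell's expression to sum to one; because
it is per-cell, normalizing batches separately and concatenating equals
normalizing the concatenation (tested). The log step is log(1 + 10⁴·p), the
Seurat-style constant. HVG ranking standardizes each gene's variance against
a robust mean–variance trend — median log-variance in quantile bins of
log-mean, interpolated — so single extreme genes cannot drag the trend;
ties break by gene order. Scaling uses the sample (n−1) standard deviation;
zero-variance genes become zero columns and are dropped before PCA. PCA
signs follow a deterministic convention (largest-magnitude loading positive),
making the whole chain bit-stable.

## Simulator

The generator emulates a bifurcating differentiation time course: 7 ideal
type profiles on a tree S → A/B → A1/A2, B1/B2 over 200 genes; intermediate
cells on an edge use θ·parent + (1−θ)·child. Seven samples over four days
follow the canonical design (1/2/2/2 samples per day, each half "earlier"
half "later" states, branches split evenly). Each sample is a batch: one
shared random set of 40 genes receives i.i.d. N(0, sd) additive components
per batch on the Poisson-mean scale, per-cell N(0, 0.5) noise is added,
means are clipped at zero, and counts are drawn Poisson.

Choices where no canonical value exists:

* **Ideal profiles.** Stem profile Gamma(shape 2, scale 2) per gene (mean ≈ 4
  counts); each child multiplies its parent by LogNormal(0, 0.5) factors.
  This keeps profiles nonnegative, distinct, and correlated along the tree
  (child–parent correlation exceeds cross-branch correlation, tested over
  20 seeds).
* **θ ranges.** Pure stages use θ = 1; transitional stages draw
  θ ~ U(0.25, 0.75), and the ambiguous-label band is the same interval, so
  every transitional draw keeps its "parent -> child" label and the label
  vocabulary matches the trajectory structure.
* **Batch-effect scale.** Default sd 3 on the count-mean scale. This is a
  calibration, not an estimate: the additive shift must compete with Poisson
  sampling noise (sd ≈ 2 at the simulated expression level) for the batch
  effect to be visible in the embedding at all. At sd 3 — the smallest
  round value that does it — the uncorrected PC embedding shows the
  qualitative pathology the method targets (terminal types fragment into
  per-sample clusters, batch silhouette well below 1) while biology remains
  recoverable. The scale is a parameter; studies of weaker or stronger
  batch effects set it directly.
* **Order of operations.** The additive shift applies to the Poisson mean
  before clipping at zero, since Poisson means must be nonnegative.
* **Cells per sample.** Default 300; 500 in the shift-recovery check where
  tighter mean estimates are needed.

What the simulator does *not* model: dropout/zero-inflation, library-size
variation beyond Poisson sampling, nonlinear (non-additive) batch effects,
and real-data complications such as unbalanced cell-type abundances across
replicates. Benchmarks passing on these simulations therefore show the
mechanism works where its assumptions hold, not that it wins on any real
dataset.

## Benchmark

The four scores are reimplemented from their standard definitions (not
numerically pinned to any external benchmark package): silhouette widths
come from scikit-learn, rescaled (s+1)/2 for the two bio-conservation
scores; the batch score is the mean over cells of 1 − |s| with batches as
labels within each cell-type group (groups with a single batch are skipped);
graph connectivity is the mean over types of the largest-component fraction
of the type-induced symmetrized kNN subgraph. Isolated labels are those
present in the minimum number of batches, ties keeping all. The aggregate is
the plain arithmetic mean of the four. Above 20,000 cells the silhouette
scores use a deterministic subsample. All metrics are checked against
brute-force oracles (O(n²) silhouette, union-find connectivity) and for
rotation/translation/relabeling invariance.

## Study sizes

The simulation study runs the 7-sample design at 300 cells per sample
(2100 cells), 200 genes, 150 HVGs, 30 PCs, over 5 replicate seeds — large
enough for stable silhouette and connectivity estimates while the full test
suite stays interactive (seconds, not minutes). Shift recovery uses 500
cells per sample.

## Known limitations

* The locality assumption conflates fast biology with batch effect when
  consecutive samples differ strongly; the length scale only trades off, it
  cannot fix, this identifiability limit.
* Σ̃ mixes batch and biological cross-batch variance; whitening therefore
  also slightly compresses true biological directions (visible in the
  simulation study as a small drop in the bio-conservation silhouette that
  the batch-mixing gain outweighs).
* Linear metric only: kernelized or consensus variants are out of scope.
* No comparator integration methods (CCA anchors, Harmony, scVI, Limma) are
  bundled; the benchmark compares against the uncorrected embedding.
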