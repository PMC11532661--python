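# Methods

This note documents the model implemented by `scmvcc`, the defaults it
ships with and why, the behaviour of the synthetic-data generator, and the
numerical choices that matter for reproducing its results.

## Model

The input is a cells × genes matrix of non-negative counts `X ∈ R^{n×m}`.
Preprocessing follows the standard single-cell recipe: cells expressing
fewer than `min_genes_per_cell` genes and genes detected in fewer than
`min_cells_per_gene` cells are dropped (cell filter first, so removing
empty cells cannot resurrect a gene); each cell is scaled to a common total
`target_sum` and transformed by `log(1+x)`; the top `n_top_genes` genes are
kept, ranked either by Seurat-style normalized dispersion (default) or by
total expression, with lexicographic gene-id tie-breaks so the selection is
independent of input gene order; finally each retained gene is standardized
to zero mean and unit variance (see *Why scaling matters* below).

**Shallow views.** From Euclidean distances `d_ij` between preprocessed
cells we build (i) a kNN graph: each cell points at its `k_knn` nearest
other cells, ties broken toward the lower index, and the directed graph is
symmetrized by union so no cell can be isolated; and (ii) a kernel graph:
the adaptive-bandwidth Gaussian affinity

    ā_ij = ½ [ exp(−d_ij / 2σ(i)²) + exp(−d_ij / 2σ(j)²) ]

with σ(i) the distance from cell i to its `k_bw`-th nearest neighbour, is
thresholded to each cell's `k_dm` strongest affinities and symmetrized the
same way. The affinity uses the *linear* distance in the exponent
numerator; `dm_squared_distance=True` switches to the conventional squared
form, and `bandwidth_mode="mean_knn_dist"` averages the `k_bw` nearest
distances instead of taking the last one. The adaptive bandwidth lets cells
in sparse regions reach further than cells in dense regions, which is why
the kernel graph typically carries at least as many union edges as the kNN
graph on data with heterogeneous density.

**Deep views.** Each adjacency `A` yields the low-pass filter
`H = Ĉ^{-1/2}(A+I)Ĉ^{-1/2}` (the symmetrically normalized self-loop
adjacency; spectrum in [−1, 1]), and `t = glf_layers` applications smooth
the features: `F = H^t X`, computed by repeated multiplication, never by an
explicit matrix power. The four (adjacency, features) pairs
`(A_knn,F_knn), (A_knn,F_dm), (A_dm,F_knn), (A_dm,F_dm)` form two groups
that share an adjacency within each group.

**Encoder and losses.** One shared two-layer GCN with softmax output of
width c (the target cluster count) encodes all four views; rows are then
L2-normalized, so each latent row lies on the unit sphere and each latent
column can be read as a soft cluster indicator. Training minimizes
`α·l_s + β·l_con + γ·l_cell`:

* `l_con` contrasts the c *columns* of the paired latents within each group
  with an NT-Xent loss on cosine similarity at temperature τ (both
  directions, averaged). Matched cluster columns across views attract; the
  other columns of both views repel.
* `l_s` compares the cross-view similarity matrices `S^{(1,2)} = Z¹(Z²)ᵀ`
  and `S^{(3,4)} = Z³(Z⁴)ᵀ` entrywise against the self-loop adjacencies
  `Â = A + I`. Because `Â` is 0/1, the indicator-split sum (edges toward 1,
  non-edges toward 0) is exactly `(1/n²)‖S − Â‖²_F`, which is how it is
  computed; tests verify the equality against the literal double loop.
* `l_cell` applies the same NT-Xent contrast to the n *rows* of the two
  similarity matrices (cells as instances, both directions). The instance
  axis is a genuinely open choice; rows are used because each row of S is a
  cell's similarity profile, and the option `cell_contrast_axis` could be
  generalized if needed. Internally the row contrast is the column contrast
  of the transposed matrices, so a single kernel serves both losses.

Two interface switches exist for exploring alternatives:
`per_group_encoders=True` gives each view group its own weight set instead
of one shared encoder, and `cell_contrast_axis="columns"` contrasts the
columns of the similarity matrices instead of the rows. Both default to the
shared/rows behaviour described above.

**Fusion and clustering.** The four latents are fused in two stages:
group-wise means `(Z¹+Z²)/2` and `(Z³+Z⁴)/2`, concatenated column-wise to
`Z_cat ∈ R^{n×2c}`. A 2-layer perceptron projection of `Z_cat` exists
behind `project_final(mode="mlp")`, but the default is the identity: no
term of the training objective touches the projected output, so the
perceptron would stay at its random initialization and only inject noise
between training and k-means. Users who attach their own training signal to
the projection can switch the mode on. k-means (k-means++, 20 restarts, 300
iterations, seed-deterministic) on `Z_cat` gives the final labels.

**Evaluation.** ACC is the matched fraction under the optimal one-to-one
cluster↔class assignment (Hungarian algorithm on the contingency table);
NMI uses arithmetic-mean normalization; ARI and FMI are the standard
contingency-table forms. All four are invariant to relabeling of either
partition.

## Defaults and their rationale

| parameter | default | notes |
|---|---|---|
| `min_genes_per_cell` / `min_cells_per_gene` | 200 / 3 | common single-cell practice; set lower for small matrices |
| `target_sum` | 1e4 | standard library-size normalization |
| `n_top_genes` | 2000 | 2000–3000 is the usual highly-variable window |
| `k_knn`, `k_dm`, `k_bw` | 15 | the conventional neighbourhood size at a few hundred to a few thousand cells |
| `glf_layers` (t) | 4 | deep enough to smooth within clusters; more layers over-smooth |
| α, β, γ | 1.0, 1.0, 0.5 | structural and group terms carry full weight; the cell-level contrast is a softer alignment term |
| τ | 0.5 | usual NT-Xent temperature range |
| `hidden_dim` | 256 | |
| optimizer | Adam, lr 0.01, 200 epochs, full batch | graph losses couple all cells, so there is no meaningful minibatch |
| weight init | Glorot uniform, seed-controlled | |
| k-means | 20 restarts, 300 iters | |

## Why scaling matters

On log-normalized data every cell's feature vector shares one dominant
mean-expression direction, so the smoothed features are nearly rank-one and
the encoder's initial logits point every cell at the *same* softmax corner.
Training then has to peel clusters off that corner one at a time, and the
softmax saturates (logit gaps beyond ~15) before the last split happens —
gradients vanish and the run freezes with merged clusters. Standardizing
each gene after selection removes the shared direction; initial cluster
assignments start diverse, the populations separate simultaneously, and
full-batch Adam at lr 0.01 converges reliably. This is the same reason the
standard single-cell toolkits scale features before neighbourhood graphs
and embeddings. `scale_genes=False` restores the unscaled behaviour for
comparison.

## Synthetic data

`simulate_counts` emulates the mechanism of Splatter-type simulators:

* a log-normal baseline of relative gene means (`baseline_sigma = 1`);
* per cluster, a `de_prob` fraction of genes is differentially expressed,
  with log-normal fold changes of mean `de_fold` (log-sd
  `de_fold_sigma = 0.4`) applied up or down with equal probability;
* per cell, a log-normal library size (`mean_library_size = 2000`,
  log-sd `libsize_sigma = 0.2`) scales the cluster's normalized profile
  into expected counts;
* counts are gamma–Poisson (negative binomial) with dispersion 0.2;
* technical dropout zeroes each entry with probability
  `expit(shape·(dropout_mid − log μ))` — at the default midpoint 0 a gene
  with expected count 1 loses about half its measurements, and
  `dropout_mid = −inf` disables dropout entirely. Raising the midpoint
  raises the zero fraction monotonically.

Cluster sizes are balanced (remainder to the last cluster) unless
`proportions` is given, which also produces small-cluster regimes. The
default fixture (300 cells × 500 genes, 3 clusters, `de_prob 0.3`,
`de_fold 2`) has ~45% zeros and populations that are linearly separable but
not trivially so: raw-space silhouette of the true labels is only ~0.07,
while the distance structure supports full recovery.

What the generator does *not* emulate: batch effects, expression paths or
trajectories, mean–variance (BCV) trends beyond a constant dispersion,
doublets, or ambient contamination. Passing tests on this generator
therefore demonstrate correct mechanics and recoverability under clean
cluster structure, not robustness to every artefact of real experiments.

## Numerical choices

* All computation is float64 on CPU; fixed seeds give bit-identical runs.
* Gradients come from a small in-repo reverse-mode autodiff core
  (`scmvcc.autodiff`) written for exactly the operator set the objective
  needs; it is validated against central finite differences (relative
  error < 1e-3 on the training objective, typically ~1e-5).
* Softmax subtracts the row maximum before exponentiation; cosine
  similarities floor the squared-norm at 1e-12; zero kernel bandwidths
  (duplicate cells) are floored at a machine-epsilon-scaled constant with a
  logged warning.
* Top-k selections break ties toward the lower cell index everywhere, so
  graph construction is deterministic and permutation-equivariant.
* Training aborts with a diagnostic naming the offending term if any loss
  becomes non-finite.
* Problem sizes used by the test suite and the acceptance script (up to
  300 cells × 500 genes, five seeds) keep a full run in the low minutes on
  one CPU core; the pipeline itself handles a few thousand cells in dense
  float64 without further changes.

## Known limitations

* The encoder output width is tied to the cluster count c, so c must be
  supplied by the user; the method does not estimate it.
* At the default lr 0.01 roughly one seed in five on the reference fixture
  still converges to a partially merged state (two populations sharing a
  softmax corner); the loss trace makes such runs visible (their final
  total stays well above that of fully separated runs).
* The fusion perceptron is untrained by design (see above); enabling it
  without an attached loss degrades clustering.
* Dense n × n matrices bound practical problem size to roughly 10⁴ cells
  in 8 GiB.
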