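# scmvcc

Multi-level multi-view graph contrastive clustering for single-cell RNA-seq
count matrices.

Clustering cells by expression profile is a core step of scRNA-seq analysis,
and no single representation of the data captures both its linear and
nonlinear neighbourhood structure. `scmvcc` builds **two shallow graph
views** of the cell population — a k-nearest-neighbour graph in Euclidean
space, `A_knn`, and a graph thresholded from an adaptive-bandwidth Gaussian
kernel affinity, `A_dm` — and turns each into a low-pass **graph Laplacian
filter**

```
H = Ĉ^{-1/2} (A + I) Ĉ^{-1/2},        Ĉ = diag degree of A + I,
```

whose t-fold application smooths the expression matrix, `F = H^t X`. Pairing
the two adjacencies with the two smoothed feature matrices yields four
**deep views** in two groups (group one: `(A_knn, F_knn)`, `(A_knn, F_dm)`;
group two: `(A_dm, F_knn)`, `(A_dm, F_dm)`). A shared two-layer GCN encoder

```
Z = softmax( Ân · ReLU( Ân F W₁ ) · W₂ ),     Ân = D̂^{-1/2}(A+I)D̂^{-1/2}
```

maps every view to an n × c latent (c = number of clusters), trained
full-batch with three losses:

* `l_con` — NT-Xent contrast over the c latent **columns** between the two
  views of each group (cosine similarity, temperature τ);
* `l_s` — structural consistency: `(1/n²)‖Z^a(Z^b)ᵀ − Â‖²_F`, pushing
  cross-view cell similarities toward the self-loop adjacency;
* `l_cell` — the same NT-Xent contrast applied to the n **rows** of the two
  cross-view similarity matrices.

The total objective is `α·l_s + β·l_con + γ·l_cell` (defaults 1.0, 1.0,
0.5). After training, group-wise means of the four latents are concatenated
into `Z_cat ∈ R^{n×2c}` and clustered with k-means; agreement with reference
labels is reported as Hungarian-matched accuracy (ACC), NMI, ARI and FMI.

A built-in simulator draws Splatter-style clustered counts (log-normal gene
means, per-cluster fold changes, negative-binomial sampling, logistic
dropout) so the entire pipeline is testable without downloads.

## Worked example

```bash
scmvcc simulate --n-cells 300 --n-genes 500 --n-clusters 3 --seed 2 --out-dir sim/
scmvcc run sim/counts.csv --clusters 3 --truth sim/truth_labels.tsv \
       --seed 2 --out-dir out/
```

The `run` command prints the metrics it wrote to `out/metrics.json`:

```json
{
  "acc": 1.0,
  "nmi": 1.0,
  "ari": 1.0,
  "fmi": 1.0
}
```

meaning the pipeline assigned every one of the 299 retained cells to the
correct simulated population (ACC of 1.0 after optimal cluster↔class
matching; mutual-information and pair-counting agreement likewise perfect).
`out/` also holds the cluster labels (`labels.tsv`), the fused embedding,
the per-epoch loss trace, and a `manifest.json` (config snapshot, seed,
input checksum, timings) that makes the run reproducible from the output
directory alone. Ablation variants — e.g. `--ablation no-graph` to replace
graph aggregation with an identity, or `--ablation no-structural` to drop
`l_s` — expose the contribution of each component.

The same pipeline is available as a library:

```python
from scmvcc import SimSpec, simulate_counts, run_pipeline

x, truth = simulate_counts(SimSpec(seed=2))
res = run_pipeline(x, n_clusters=3, truth=truth, seed=2)
print(res.result.metrics.as_dict())
```

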