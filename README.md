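# sctransfer

Transfer learning for single-cell RNA-seq clustering.

Small, tissue- or disease-specific scRNA-seq datasets are hard to
cluster: with only a few hundred cells, rare populations blur into their
neighbours. `sctransfer` improves the clustering of such a small,
unlabeled **target** dataset by transferring structure from a large,
well-annotated **source** (reference) dataset — without concatenating
the two and without restricting the target to the source's cell types.

## The method

Given a source `X_src ∈ R^{g×n_src}` with cluster labels `y_src` and a
target `X_trg ∈ R^{g×n_trg}` over the same genes (both log scale):

1. **Learn a dictionary.** Elastic-net regularized NMF factorizes the
   source,

   ```
   min_{H,W≥0}  ½‖X_src − HW‖²_F + αλ(‖vec H‖₁+‖vec W‖₁)
                + (α/2)(1−λ)(‖H‖²_F+‖W‖²_F),
   ```

   with `W` warm-started from the one-hot encoding of `y_src`, so the
   columns of the dictionary `H ∈ R^{g×k}` align with the annotated cell
   types. `H` is independent of the number of cells and can translate
   between datasets. (Without labels, source labels are first generated
   by NMF clustering.)

2. **Project the target.** `W_trg = argmin_{W≥0} ½‖X_trg − H W‖²_F`,
   binarized to hard assignments `W′` (column-wise maxima).

3. **Mix.** `X_new(θ) = θ·H W′ + (1−θ)·X_trg`. The mixture parameter
   `θ ∈ [0,1]` controls how strongly source knowledge reshapes the
   target.

4. **Cluster** `X_new(θ)` with SC3-style consensus clustering (k-means
   over Euclidean/Pearson/Spearman distances under PCA and graph-
   Laplacian transforms, averaged into a consensus matrix and cut
   hierarchically at k).

θ is chosen automatically: for each grid value the predicted labels are
scored by kernel target alignment (KTA) against the target's cell
kernel, and the best-scoring θ wins. When the two datasets share no
populations the selector settles on a low θ, so the transfer cannot
hurt; when they overlap it mixes aggressively.

The package also ships the hierarchical negative-binomial count
simulator used to validate the method (eight cell populations under
five top-level groups, three source/target overlap regimes), the
`TargetCluster`/`ConcatenateCluster` baselines, an ARI evaluation
harness with confidence intervals, and a robustness-counting protocol.
See `docs/methods.md` for the full model description and all
calibration choices.

## Worked example

Simulate a tissue, split it into a labeled source and an unlabeled
target with fully shared cluster structure, and transfer:

```python
import numpy as np
import sctransfer as st
from sctransfer.preprocess import log_transform

sim = st.SimConfig(n_genes=5000, n_cells=900, n_src=500, target_sizes=(200,))
data = st.generate_dataset(sim, seed=7)
src, trg = st.split_source_target(data, "complete", 500, 200, seed=8)
X_src, X_trg = log_transform(src.X), log_transform(trg.X)
y_src = np.unique(src.y, return_inverse=True)[1]

model = st.TransferClusterModel(
    X_trg, X_src, y_src, theta_grid=(0.1, 0.3, 0.5, 0.7, 0.9), seed=0
)
res = model.fit()
print(res.summary())
```

```
Transfer clustering results
===========================
genes (aligned):        5000
source cells:           500
target cells:           200
dictionary atoms (k):   8
target clusters:        8
elastic net alpha/lam:  1 / 0.5
NMF iterations:         137
selected theta:         0.1

theta   KTA score
 0.10   0.207855  <- selected
 0.30   0.189868
 0.50   0.177338
 0.70   0.166588
 0.90   0.161869

target cluster sizes:   0:63 1:14 2:16 3:17 4:14 5:31 6:18 7:27
```

`res.labels_` holds the predicted target clusters, `res.theta_` the
selected mixture weight, and `res.score_table()` the KTA profile
(`res.plot_kta()` draws it). Against the simulation's ground truth:

```python
print(st.adjusted_rand_index(trg.y, res.labels_))          # 0.436
lab0 = st.target_cluster(X_trg, st.SC3Config(k=8, seed=0))
print(st.adjusted_rand_index(trg.y, lab0))                 # 0.217
```

Even a mild mixture (θ = 0.1) doubles the adjusted Rand index over
clustering the 200-cell target alone; at the full study scale
(10 000 genes) the transfer reaches mean ARI ≈ 0.96–0.99 versus
≈ 0.42–0.72 for the target-only baseline.

The same pipeline is available from the shell:

```sh
sctransfer simulate --out-dir sim --seed 7 --n-genes 2000 --n-cells 600
sctransfer transfer --src-x src.tsv --src-y src_labels.tsv --trg-x trg.tsv \
    --k 8 --seed 0 --out-dir results/
sctransfer cluster --x trg.tsv --k 8 --out-dir results/
sctransfer evaluate --config experiment.yaml --out-dir study/
```

Every command writes a `run_record.json` (resolved configuration, seeds,
input checksums) sufficient to re-execute the run.

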