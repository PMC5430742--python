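# netbc — network-aided bi-clustering of gene expression data

`netbc` partitions a genes × samples expression matrix **simultaneously**
into gene clusters and sample clusters, producing a checkerboard of
non-overlapping bi-clusters.  It is aimed at cancer-subtype discovery:
patients of a subtype share expression patterns over a *subset* of genes,
so one-dimensional clustering of samples alone misses the structure, and a
gene-interaction network carries prior knowledge about which genes matter.

## The model

Given `G ∈ R^{m×n}`, nonnegative indicator matrices `R` (m×k, rows summing
to 1) and `C` (n×d) encode the two partitions.  With projectors
`P_R = R(RᵀR)⁻¹Rᵀ` and `P_C = C(CᵀC)⁻¹Cᵀ`, the fit minimises the weighted
sum-squared residue

```
Φ(R, C) = ‖(I − P_R) G (I − P_C)‖²_W
        = Σ_ij W_ii (g_ij − g̃_iJ − g̃_Ij + g̃_IJ)² ,
```

the squared difference of every entry from its block's row mean, column
mean and block mean.  This residue is zero not only for constant blocks but
for row-constant, column-constant and additive-coherent ones, so the method
finds bi-clusters with coherent *trends*, not just constant values.

The diagonal weights `W_ii = w_i` come from a PageRank-style recursion over
the gene-interaction network (`P` binary adjacency, `D` column degrees,
`e` per-gene expression variation):

```
w = (1 − θ) e + θ P D⁻¹ w
```

`θ = 0` weights genes by expression variation alone; `θ → 1` by network
connectivity; `0.85` is the customary damping.  Optimisation alternates
multiplicative KKT updates of `R` and `C` (safeguarded so the objective
trace is non-increasing), then hardens by per-row argmax.  The number of
clusters `(k, d)` is chosen by consensus stability over repeated runs,
scored with the cophenetic correlation coefficient.

See `docs/methods.md` for numerical details, design choices and known
limitations.

## Worked example

```python
import numpy as np
from netbc import (NetBC, make_checkerboard, generate_structured_network,
                   compute_weights, rand_score, select_k_d)

# 60 genes x 30 samples, 3 gene groups x 2 sample groups,
# additive-coherent blocks, measurement noise sigma = 0.1
expr, true_rows, true_cols = make_checkerboard(
    60, 30, k=3, d=2, kind="additive", sigma=0.1, seed=7)

model = NetBC(3, 2, init="kmeans", random_state=7).fit(expr)
print("gene RI  :", rand_score(true_rows, model.row_labels_))
print("sample RI:", rand_score(true_cols, model.column_labels_))
print("objective: %.2f after %d iterations"
      % (model.objective_trace_[-1], model.n_iter_))

# network-aware gene weights: hub genes gain, isolated noisy genes lose
net = generate_structured_network(60, range(20), 0.2, 0.02, seed=7,
                                  gene_ids=expr.gene_ids)
w = compute_weights(expr, network=net, theta=0.85)
print("weights  : %.2f .. %.2f (mean 1)" % (w.w.min(), w.w.max()))

# choose (k, d) by consensus stability on symmetric constant-block data
mu = 1.5 * np.array([[1, 0], [-0.5, 3**0.5 / 2], [-0.5, -(3**0.5) / 2]])
sel_expr, _, _ = make_checkerboard(60, 30, 3, 2, kind="constant",
                                   sigma=0.1, seed=7, block_means=mu)
sel = select_k_d(sel_expr, [2, 3, 4], [2, 3], n_runs=10, random_state=7)
print("selected :", (sel.k, sel.d))
```

Output:

```
gene RI  : 1.0
sample RI: 1.0
objective: 14.87 after 300 iterations
weights  : 0.17 .. 2.56 (mean 1)
selected : (3, 2)
```

Both partitions are recovered exactly (Rand index 1.0); the residual
objective ≈ 14.9 is the noise floor (≈ m·n·σ² after double centring); the
GeneRank weights spread by a factor ~15 between poorly connected and hub
genes; and the stability search returns the true (3, 2).

A command-line interface mirrors the library:

```
netbc simulate --type additive --m 100 --n 50 --seed 1 --out sim/
netbc run --expression sim/expression.tsv --k 4 --d 4 --init kmeans \
          --seed 1 --out fit/
netbc weights --expression expr.tsv --network edges.tsv --theta 0.85 \
          --out weights.tsv
netbc select --expression expr.tsv --k-min 2 --k-max 6 --d-min 2 --d-max 4 \
          --runs 20 --out grid.tsv
netbc evaluate --pred fit/biclusters.json --truth sim/biclusters.json
```

Expression files are TSV (header = sample ids, first column = gene ids);
networks are two-column TSV edge lists.

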