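# Methods

## Model

The data are a real-valued expression matrix `G` with `m` genes (rows) and
`n` samples (columns).  The model is a *checkerboard* bi-clustering: a
simultaneous partition of the genes into `k` clusters and the samples into
`d` clusters, inducing `k x d` non-overlapping blocks.  A block is
considered coherent when its entries follow a constant, row-constant,
column-constant or additive pattern; all four make the classical
sum-squared residue vanish:

    h_ij = (g_ij - rowmean_i - colmean_j + blockmean)^2 ,

with the means taken within the block.  Multiplicative-coherent blocks
(`g_ij = u * alpha_i * beta_j`) do not have zero residue in general and are
only recovered approximately.

Cluster membership is encoded by nonnegative indicator matrices `R`
(`m x k`, rows summing to one) and `C` (`n x d`).  With the projectors
`P_R = R (R'R)^{-1} R'` and `P_C = C (C'C)^{-1} C'` the fitted objective is

    Phi(R, C) = || (I - P_R) G (I - P_C) ||^2_W ,

the squared Frobenius norm of the double-centred residual with each gene
row scaled by a weight `W_ii = w_i`.  For hard indicators, `P_R G` is
exactly the per-column mean over each gene cluster, so `Phi` equals the sum
of the blockwise residues above — the test suite asserts this equivalence
against an explicit double-loop oracle at 1e-10 relative tolerance, which
is why the Gram inverses are computed by exact solve (a ridge is added only
when the solve fails on a singular Gram matrix).

## Gene weights

Genes are weighted by a PageRank-style recursion over the interaction
network: with `P` the binary adjacency (column degrees `deg_j`, zero-degree
columns dropped from the propagation) and `e` the per-gene expression
variation,

    w = (1 - theta) e + theta P D^{-1} w .

`e` is the mean absolute deviation of a gene about its row mean (standard
deviation and range are available as alternatives).  `theta` in [0, 1]
balances expression against network: 0 ignores the network, 1 ignores
expression.  0.85 is the customary damping value; no automatic selection of
`theta` is attempted.  The direct sparse solve is used for `theta < 1`; the
fixed-point iteration covers `theta = 1` and serves as an independent
cross-check (the two agree to 1e-8 max-norm on 200-gene networks).  On a
bipartite network the `theta = 1` iteration can oscillate; the solver then
returns its last iterate with a warning.  Weights are rescaled to mean one
— the objective is invariant to their global scale, and a fixed scale makes
objective values comparable across `theta`.

## Optimisation

`R` and `C` are updated alternately by multiplicative rules of the form
`x <- x * sqrt(numerator / denominator)` derived from the KKT conditions of
each subproblem, holding the other factor — and the auxiliary residual
matrices — fixed.  Three numerical choices matter:

* **Floors.**  Numerators and denominators are floored at `eps = 1e-12`.
  Flooring only the denominator (the common convention) lets a zero
  numerator permanently kill an indicator entry; whole rows can die and
  renormalisation then divides by zero.
* **Safeguard.**  Because the auxiliary matrices depend on the variable
  being updated, a raw step is *not* guaranteed to decrease `Phi`; in
  practice the raw alternation can oscillate with per-step increases up to
  ~0.2.  `fit` therefore accepts a half-step only when it does not increase
  the objective, which makes the recorded trace non-increasing by
  construction.  Single raw steps from typical initialisations do decrease
  the objective and are tested as such.
* **Renormalisation.**  Indicator rows are renormalised to sum to one after
  every update, enforcing the feasible set of the model (switchable off).

Iteration stops after `max_iter = 300` rounds or when the relative
objective decrease stays below `1e-8` for five consecutive rounds.  Hard
labels are the per-row argmax (ties to the smallest index); a cluster left
empty by hardening is repaired by moving in the item with the largest
weighted residue.

### A degeneracy worth knowing about

`Phi` depends on `R` only through the column space of `R` (it is invariant
under `R -> R T` for any invertible `T`), and likewise for `C`.  The
nonnegativity and row-sum constraints break this invariance only partially:
from a generic random start the optimiser happily converges to a nonneg
*mixture* of cluster indicators whose argmax labels are essentially
arbitrary, even when the objective reaches its global minimum.  k-means
initialisation anchors the iteration near the one-hot cone and avoids the
problem; it is the recommended mode whenever label recovery is the goal.
Random initialisation remains available and matches the historical
protocol, but its hardened labels should be interpreted with care.

A second structural fact: for constant or row-constant blocks the residue
is *flat* in the row partition (any regrouping of rows still yields
row-constant blocks), and symmetrically for column-constant blocks.  On
such data one of the two partitions is simply not identified by the
objective; identification must come from the data generator (see below) or
prior structure.

## Model selection

For each candidate `(k, d)` the fit is repeated `n_runs` times; gene and
sample co-assignment matrices are averaged into consensus matrices, and
stability is scored by the cophenetic correlation of `1 - M` under average
linkage.  The selected `(k, d)` maximises the mean of the two coefficients.
Two choices differ from the obvious defaults, both forced by the
degeneracies above:

* Consensus runs use a **single-start k-means initialisation** rather than
  random indicators: random starts give partially arbitrary labels at every
  `(k, d)` (flat scores ~0.8 across the whole grid), whereas one random
  k-means start varies merge/split choices at a wrong `(k, d)` while
  reliably recovering a true, well-separated partition.
* **Exact score ties break towards the larger model.**  A merge of
  well-separated clusters is reproducible by construction and scores
  exactly 1; preferring the smaller `k` on ties therefore systematically
  underfits clean data.  Equal stability carries no evidence for the
  smaller model, while the larger one explains more structure at the same
  reproducibility.  (Overfit ties are possible only on essentially
  noise-free data, where any amount of measurement noise restores
  discrimination.)

`k = 1` makes the gene consensus all-ones and the coefficient degenerate
(returned as 1 with a warning); grids should start at 2.

## Synthetic data

Two generators with different purposes:

**Implant benchmark** (`make_implanted_dataset`): N(0, 1) background with a
few non-overlapping submatrices rewritten by one of the five pattern rules,
pattern values drawn from the background itself (constant: one entry copied
everywhere; row/column-constant: one base column/row copied; additive: base
row + N(0, 2^2) shifts; multiplicative: base row x (+/-)uniform[0.5, 2]
scales), plus optional N(0, sigma^2) noise.  Default geometry: 100 x 50
with three 15 x 8 implants.  These implants occupy ~2.4 % of the matrix at
the same amplitude as the background.  Measured consequence: the truth
partition is *not* the minimiser of the checkerboard objective under this
geometry — partitions that split the large background group achieve a lower
weighted residue than the truth, for every initialisation, weighting and
renormalisation variant tried, including a block-diagonal tiling variant.
The benchmark is therefore reported as what it is: a stress test that this
family of global checkerboard methods does not pass at these amplitudes
(local-search bi-cluster miners are the right tool there).  Discovered
bi-clusters for this benchmark are the `n` most coherent blocks (smallest
mean squared residue), with `n` the number of implanted bi-clusters.

**Checkerboard generator** (`make_checkerboard`): every block of a full
`k x d` tiling follows one pattern rule applied to
`0.25 * background + mu_ab`, with block means `mu_ab ~ N(0, 3^2)` by
default or an explicit matrix (e.g. equilateral-triangle means for
model-selection studies, where no merge of row groups is privileged).  The
offsets make both partitions statistically identifiable — necessary because
of the flat directions noted above — while each block remains exactly its
pattern type, so noiseless data of types (i)-(iv) still have identically
zero residue at the truth.  What passing recovery tests on this generator
shows: the optimiser finds the truth when the data identify it.  What it
does not show: performance under the implant regime, dropout, batch
effects, or heavy-tailed real expression noise.

The noisy-gene protocol replaces the lowest-weight genes with uniform
values spanning the matrix range; the structured network connects any pair
with at least one "informative" endpoint with probability `p_hub` and all
other pairs with `p_background`.  Network perturbation deletes/adds/rewires
uniformly random (non-)edges, preserving symmetry and never introducing
self-loops or duplicates.

## Benchmark protocol sizes

The protocols in `netbc.benchmarks` (also run by `scripts/acceptance.py`)
use: 100 random instances (m <= 50, n <= 20) for the residue oracle;
10 seeds x 2 inits x 5 pattern types at sigma = 0.1 for monotonicity;
200-gene networks for the weighting solvers; 60 x 30 checkerboards (3 x 2)
for recovery and model selection (5 repetitions, 10 consensus runs each,
grid k in 2..4, d in 2..3, equilateral block means scaled by 1.5,
sigma = 0.1); the 100 x 50 implant benchmark at sigma = 0.05; and the
noisy-gene experiment on 100 x 40 checkerboards (30 noisy genes,
p_hub = 0.2, p_background = 0.02, 10 seeds), with a 10 %-edge-rewiring
variant.  A full run takes about half a minute on one CPU.

## Known limitations

* Random-start label recovery is unreliable by construction (mixing
  degeneracy); use k-means initialisation or consensus.
* Small, background-dominated implants are below the objective's detection
  threshold (see above).
* Multiplicative-coherent row structure is not a nullspace of the residue
  and is recovered only approximately.
* No missing-value handling inside the solver; loaders reject incomplete
  matrices.
* Bi-clusters are non-overlapping by design; arbitrarily positioned or
  overlapping bi-clusters are out of scope.
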