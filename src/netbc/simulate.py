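"""Synthetic benchmarks: implanted bi-clusters, checkerboards, noisy genes
and network perturbations.

Two generators are provided.

``make_implanted_dataset`` follows the classical implant protocol: a
standard-Gaussian background matrix in which a few non-overlapping
submatrices are rewritten according to one of five pattern rules —
(i) constant (one randomly chosen entry copied everywhere), (ii)
row-constant (a random base column copied across columns), (iii)
column-constant (a random base row copied across rows), (iv) additive
coherent (base row plus per-row shifts), (v) multiplicative coherent (base
row times per-row scales).  Because the pattern values are drawn from the
same N(0, 1) scale as the background, these implants are weak signals; the
benchmark probes what a global checkerboard objective can and cannot see.

``make_checkerboard`` produces fully tiled checkerboard data: every
(row group x column group) block follows one pattern rule, applied to a
down-scaled background plus a block-specific mean offset.  Offsets make
both partitions statistically identifiable — for constant, row-constant
and column-constant patterns the sum-squared residue is flat in one of the
partitions, so identifiability must come from the data, not the objective.
Noiseless checkerboards of types (i)-(iv) have exactly zero residue at the
true partition.

Additive shifts default to N(0, 2^2) and multiplicative scales to
+/- uniform[0.5, 2]: large enough to stand out from the N(0, 1) background,
small enough to keep values in a realistic log-expression range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, GeneNetwork
from .metrics import BiCluster
from .weighting import GeneWeights

__all__ = [
    "PATTERN_KINDS",
    "ImplantSpec",
    "generate_background",
    "implant",
    "add_noise",
    "make_implanted_dataset",
    "make_checkerboard",
    "inject_noisy_genes",
    "perturb_network",
    "generate_structured_network",
]

PATTERN_KINDS = (
    "constant",
    "row_constant",
    "column_constant",
    "additive",
    "multiplicative",
)


@dataclass
class ImplantSpec:
    """Placement and pattern of a set of non-overlapping implants."""

    kind: str
    row_sets: list[list[int]]
    col_sets: list[list[int]]
    sigma_noise: float = 0.0
    seed: int | None = None
    shift_sd: float = 2.0
    scale_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"kind must be one of {PATTERN_KINDS}, got {self.kind!r}")
        if len(self.row_sets) != len(self.col_sets):
            raise ValueError("row_sets and col_sets must have equal length")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        flat_r = [i for s in self.row_sets for i in s]
        flat_c = [j for s in self.col_sets for j in s]
        if len(flat_r) != len(set(flat_r)):
            raise ValueError("row index sets must be pairwise disjoint")
        if len(flat_c) != len(set(flat_c)):
            raise ValueError("column index sets must be pairwise disjoint")


def generate_background(m: int, n: int, seed=None) -> np.ndarray:
    """i.i.d. standard-normal background matrix."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    return np.random.default_rng(seed).standard_normal((m, n))


def _apply_pattern(
    sub: np.ndarray,
    kind: str,
    rng: np.random.Generator,
    shift_sd: float,
    scale_range: tuple[float, float],
) -> np.ndarray:
    r, c = sub.shape
    if kind == "constant":
        return np.full((r, c), sub.flat[rng.integers(sub.size)])
    if kind == "row_constant":
        return np.tile(sub[:, [rng.integers(c)]], (1, c))
    if kind == "column_constant":
        return np.tile(sub[[rng.integers(r)], :], (r, 1))
    if kind == "additive":
        b = rng.integers(r)
        shifts = rng.normal(0.0, shift_sd, size=(r, 1))
        shifts[b] = 0.0  # the base row itself stays in place
        return sub[[b], :] + shifts
    if kind == "multiplicative":
        b = rng.integers(r)
        lo, hi = scale_range
        scales = rng.uniform(lo, hi, size=(r, 1)) * rng.choice([-1.0, 1.0], size=(r, 1))
        scales[b] = 1.0
        return sub[[b], :] * scales
    raise ValueError(f"unknown pattern kind {kind!r}")


def implant(
    matrix: np.ndarray, spec: ImplantSpec
) -> tuple[np.ndarray, list[BiCluster]]:
    """Rewrite the submatrices named by ``spec`` per its pattern rule.

    Returns a modified copy and the truth bi-cluster set (integer indices).
    """
    G = np.asarray(matrix, dtype=float).copy()
    m, n = G.shape
    rng = np.random.default_rng(spec.seed)
    truth: list[BiCluster] = []
    for rows, cols in zip(spec.row_sets, spec.col_sets):
        rows = list(rows)
        cols = list(cols)
        if not rows or not cols:
            raise ValueError("empty implant index set")
        if max(rows) >= m or max(cols) >= n or min(rows) < 0 or min(cols) < 0:
            raise ValueError("implant index out of bounds")
        blk = np.ix_(rows, cols)
        G[blk] = _apply_pattern(G[blk], spec.kind, rng, spec.shift_sd, spec.scale_range)
        truth.append(BiCluster(frozenset(rows), frozenset(cols)))
    if spec.sigma_noise > 0:
        G = add_noise(G, spec.sigma_noise, seed=rng.integers(0, 2**31 - 1))
    return G, truth


def add_noise(matrix: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Add i.i.d. N(0, sigma^2) to every entry (identity at sigma = 0)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    G = np.asarray(matrix, dtype=float)
    if sigma == 0:
        return G.copy()
    rng = np.random.default_rng(seed)
    return G + rng.normal(0.0, sigma, size=G.shape)


def _ids(prefix: str, count: int) -> list[str]:
    width = len(str(count))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def make_implanted_dataset(
    m: int = 100,
    n: int = 50,
    n_biclusters: int = 3,
    bicluster_shape: tuple[int, int] = (15, 8),
    kind: str = "constant",
    sigma: float = 0.0,
    seed=None,
    shift_sd: float = 2.0,
    scale_range: tuple[float, float] = (0.5, 2.0),
) -> tuple[ExpressionMatrix, list[BiCluster], ImplantSpec]:
    """Background matrix with implants on random disjoint row/column sets.

    Truth bi-clusters are returned with the generated gene/sample
    identifiers, matching what discovery on the ExpressionMatrix yields.
    """
    bh, bw = bicluster_shape
    if n_biclusters * bh > m or n_biclusters * bw > n:
        raise ValueError("implants do not fit disjointly in the matrix")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((m, n))
    rows = rng.permutation(m)
    cols = rng.permutation(n)
    spec = ImplantSpec(
        kind=kind,
        row_sets=[sorted(rows[b * bh : (b + 1) * bh].tolist()) for b in range(n_biclusters)],
        col_sets=[sorted(cols[b * bw : (b + 1) * bw].tolist()) for b in range(n_biclusters)],
        sigma_noise=sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
        shift_sd=shift_sd,
        scale_range=scale_range,
    )
    G, truth_idx = implant(G, spec)
    gene_ids = _ids("g", m)
    sample_ids = _ids("s", n)
    expr = ExpressionMatrix(G, gene_ids, sample_ids)
    truth = [
        BiCluster(
            frozenset(gene_ids[i] for i in bc.genes),
            frozenset(sample_ids[j] for j in bc.samples),
        )
        for bc in truth_idx
    ]
    return expr, truth, spec


def _split_labels(total: int, groups: int, rng: np.random.Generator) -> np.ndarray:
    sizes = np.diff(np.linspace(0, total, groups + 1).astype(int))
    return rng.permutation(np.repeat(np.arange(groups), sizes))


def make_checkerboard(
    m: int,
    n: int,
    k: int,
    d: int,
    kind: str = "constant",
    sigma: float = 0.0,
    seed=None,
    block_means: np.ndarray | None = None,
    mean_sd: float = 3.0,
    within: float = 0.25,
    shift_sd: float = 2.0,
    scale_range: tuple[float, float] = (0.5, 2.0),
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Fully tiled k x d checkerboard with one pattern rule per block.

    Each block is ``within * background + mu_ab`` passed through the pattern
    rule, where the block means mu_ab are drawn N(0, mean_sd^2) unless an
    explicit k x d ``block_means`` matrix is given (e.g. a symmetric design
    for model-selection studies).  Row and column group labels are returned
    alongside the data.
    """
    if kind not in PATTERN_KINDS:
        raise ValueError(f"kind must be one of {PATTERN_KINDS}, got {kind!r}")
    if k > m or d > n:
        raise ValueError("more clusters than rows/columns")
    rng = np.random.default_rng(seed)
    row_labels = _split_labels(m, k, rng)
    col_labels = _split_labels(n, d, rng)
    if block_means is None:
        mu = rng.normal(0.0, mean_sd, size=(k, d))
    else:
        mu = np.asarray(block_means, dtype=float)
        if mu.shape != (k, d):
            raise ValueError(f"block_means must be {k}x{d}")
    G = rng.standard_normal((m, n))
    for a in range(k):
        for b in range(d):
            blk = np.ix_(row_labels == a, col_labels == b)
            sub = within * G[blk] + mu[a, b]
            G[blk] = _apply_pattern(sub, kind, rng, shift_sd, scale_range)
    if sigma > 0:
        G = G + rng.normal(0.0, sigma, size=(m, n))
    expr = ExpressionMatrix(G, _ids("g", m), _ids("s", n))
    return expr, row_labels, col_labels


def inject_noisy_genes(
    expr: ExpressionMatrix,
    weights: GeneWeights | np.ndarray,
    n_noisy: int,
    seed=None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Replace the ``n_noisy`` lowest-weight genes by uniform noise.

    The replacement values are i.i.d. uniform between the minimum and
    maximum of the whole matrix, destroying any structure those genes
    carried while keeping their range realistic.
    """
    w = weights.w if isinstance(weights, GeneWeights) else np.asarray(weights, float)
    m = expr.n_genes
    if w.shape != (m,):
        raise ValueError("weights length does not match gene count")
    if not 0 <= n_noisy < m:
        raise ValueError("n_noisy must be in [0, m)")
    if n_noisy == 0:
        return ExpressionMatrix(expr.values.copy(), expr.gene_ids, expr.sample_ids), []
    rng = np.random.default_rng(seed)
    order = np.argsort(w, kind="stable")
    noisy_idx = np.sort(order[:n_noisy])
    G = expr.values.copy()
    lo, hi = G.min(), G.max()
    G[noisy_idx] = rng.uniform(lo, hi, size=(n_noisy, expr.n_samples))
    noisy_ids = [expr.gene_ids[i] for i in noisy_idx]
    return ExpressionMatrix(G, expr.gene_ids, expr.sample_ids), noisy_ids


def _edge_key(i: int, j: int, directed: bool) -> tuple[int, int]:
    return (i, j) if directed else (min(i, j), max(i, j))


def perturb_network(
    net: GeneNetwork,
    n_add: int = 0,
    n_delete: int = 0,
    n_rewire: int = 0,
    seed=None,
) -> GeneNetwork:
    """Randomly add, delete and rewire edges (one delete + one add per rewire).

    Never introduces self-loops or duplicate edges; symmetry is preserved
    for undirected networks.  Raises if the edge or non-edge supply is
    insufficient.
    """
    rng = np.random.default_rng(seed)
    m = net.n_genes
    A = net.adjacency.toarray()
    directed = net.directed

    def current_edges() -> list[tuple[int, int]]:
        if directed:
            return [tuple(e) for e in np.argwhere(A > 0)]
        return [tuple(e) for e in np.argwhere(np.triu(A, 1) > 0)]

    def delete_one() -> None:
        edges = current_edges()
        if not edges:
            raise ValueError("cannot delete: no edges left")
        i, j = edges[rng.integers(len(edges))]
        A[i, j] = 0
        if not directed:
            A[j, i] = 0

    def add_one() -> None:
        for _ in range(100 * m * m):
            i, j = rng.integers(0, m, size=2)
            if i == j or A[i, j] > 0:
                continue
            A[i, j] = 1
            if not directed:
                A[j, i] = 1
            return
        raise ValueError("cannot add: no non-edge found")

    n_edges = len(current_edges())
    max_pairs = m * (m - 1) if directed else m * (m - 1) // 2
    if n_delete + n_rewire > n_edges:
        raise ValueError(
            f"need {n_delete + n_rewire} deletable edges, have {n_edges}"
        )
    if n_add > max_pairs - n_edges:
        raise ValueError(
            f"need {n_add} addable non-edges, have {max_pairs - n_edges}"
        )
    for _ in range(n_delete):
        delete_one()
    for _ in range(n_add):
        add_one()
    for _ in range(n_rewire):
        delete_one()
        add_one()
    return GeneNetwork(sp.csr_matrix(A), directed=directed, gene_ids=list(net.gene_ids))


def generate_structured_network(
    m: int,
    informative_genes,
    p_hub: float,
    p_background: float,
    seed=None,
    gene_ids: list[str] | None = None,
) -> GeneNetwork:
    """Undirected network whose informative genes are hubs.

    A pair with at least one informative endpoint is connected with
    probability ``p_hub``; all other pairs with ``p_background``.  With
    equal probabilities this reduces to an Erdos-Renyi graph.
    """
    if not 0 <= p_background <= 1 or not 0 <= p_hub <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    inf_mask = np.zeros(m, dtype=bool)
    informative = np.asarray(list(informative_genes), dtype=int)
    if informative.size and (informative.min() < 0 or informative.max() >= m):
        raise ValueError("informative gene index out of range")
    inf_mask[informative] = True
    either = inf_mask[:, None] | inf_mask[None, :]
    prob = np.where(either, p_hub, p_background)
    U = rng.uniform(size=(m, m))
    upper = np.triu(U < prob, k=1)
    A = upper.astype(float)
    A = A + A.T
    return GeneNetwork(
        sp.csr_matrix(A),
        directed=False,
        gene_ids=gene_ids if gene_ids is not None else _ids("g", m),
    )
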