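"""Checkerboard bi-clustering by weighted sum-squared residue minimisation.

The model partitions the m genes of an expression matrix G into k row
clusters and the n samples into d column clusters via nonnegative indicator
matrices R (m x k) and C (n x d).  Writing P_R = R (R^T R)^{-1} R^T and
P_C = C (C^T C)^{-1} C^T, the objective is the weighted squared Frobenius
norm of the double-centred residual

    Phi(R, C) = || (I - P_R) G (I - P_C) ||^2_W
             = sum_ij W_ii (g_ij - rowmean - colmean + blockmean)^2,

where W is diagonal with per-gene weights.  For hard indicators, P_R G is
the column-wise mean over each row cluster and G P_C the row-wise mean over
each column cluster, so each block's contribution is the classical
sum-squared residue: zero for constant, row-constant, column-constant and
additive-coherent blocks.

The objective is minimised over the continuous nonnegative relaxation by
alternating multiplicative updates derived from the KKT conditions, then
hardened by per-row argmax.  Because the auxiliary matrices of the
derivation are held fixed within each half-step, a raw step is not
guaranteed to decrease Phi; ``fit`` therefore safeguards the alternation by
accepting a half-step only when it does not increase the objective, which
makes the recorded trace non-increasing.

Note the relaxation is invariant under R -> R T for invertible T (the
projector P_R depends on R only through its column space), so from a
generic random start the optimum need not align indicator columns with
clusters; k-means initialisation anchors the iteration near the one-hot
cone and is recommended whenever cluster recovery (rather than residue
minimisation) is the goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, BiclusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix
from .metrics import BiCluster
from .weighting import GeneWeights, compute_weights

__all__ = [
    "NetBC",
    "BiClusteringResult",
    "objective",
    "residue_decomposition",
    "update_R",
    "update_C",
    "initialize_indicators",
    "fit_biclustering",
    "extract_biclusters",
    "block_mean_squared_residue",
    "top_biclusters",
]


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _gram_solve(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve (M^T M) X = B, adding a small ridge only if the Gram is singular."""
    gram = M.T @ M
    try:
        return np.linalg.solve(gram, B)
    except np.linalg.LinAlgError:
        k = gram.shape[0]
        lam = 1e-10 * (np.trace(gram) / k + 1.0)
        return np.linalg.solve(gram + lam * np.eye(k), B)


def _pos_neg(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split M = M+ - M- with M+, M- >= 0 elementwise."""
    A = np.abs(M)
    return (A + M) / 2.0, (A - M) / 2.0


def _as_weight_vector(
    weights: GeneWeights | np.ndarray | None, m: int
) -> np.ndarray:
    if weights is None:
        return np.ones(m)
    w = weights.w if isinstance(weights, GeneWeights) else np.asarray(weights, float)
    if w.shape != (m,):
        raise ValueError(f"weights have length {w.shape}, expected {m}")
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be finite and nonnegative")
    return w


# ---------------------------------------------------------------------------
# objective and residue decomposition


def residue_decomposition(
    G: np.ndarray, R: np.ndarray, C: np.ndarray
) -> dict[str, np.ndarray]:
    """Row-mean, column-mean, block-mean and residual matrices.

    For hard indicators each entry of ``row_mean`` equals the mean of G over
    the rows of that entry's row cluster in the same column (and
    symmetrically for ``col_mean``).
    """
    row_mean = R @ _gram_solve(R, R.T @ G)
    col_mean = (_gram_solve(C, (G @ C).T)).T @ C.T
    block_mean = R @ _gram_solve(R, R.T @ col_mean)
    residual = G - row_mean - col_mean + block_mean
    return {
        "row_mean": row_mean,
        "col_mean": col_mean,
        "bicluster_mean": block_mean,
        "residual": residual,
    }


def objective(
    G: np.ndarray,
    R: np.ndarray,
    C: np.ndarray,
    weights: GeneWeights | np.ndarray | None = None,
) -> float:
    """Weighted sum-squared residue Phi(R, C)."""
    G = np.asarray(G, dtype=float)
    if not np.isfinite(G).all():
        raise ValueError("data matrix contains non-finite values")
    w = _as_weight_vector(weights, G.shape[0])
    H = residue_decomposition(G, R, C)["residual"]
    return float(np.sum(w[:, None] * H * H))


# ---------------------------------------------------------------------------
# multiplicative updates


def update_R(
    G: np.ndarray,
    R: np.ndarray,
    C: np.ndarray,
    weights: GeneWeights | np.ndarray | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the row indicator matrix.

    R'_{ik} = R_{ik} * sqrt((A+ + W R B-)_{ik} / (A- + W R B+)_{ik}) with
    A = W X1 X2^T, B = X2 X2^T, X1 = G (I - P_C), X2 = (R^T R)^{-1} R^T X1.
    Both numerator and denominator are floored at ``eps``: a zero numerator
    would permanently zero out indicator entries that multiplicative updates
    cannot revive.
    """
    w = _as_weight_vector(weights, G.shape[0])
    X1 = G - (_gram_solve(C, (G @ C).T)).T @ C.T
    X2 = _gram_solve(R, R.T @ X1)
    A = (w[:, None] * X1) @ X2.T
    B = X2 @ X2.T
    Ap, An = _pos_neg(A)
    Bp, Bn = _pos_neg(B)
    WR = w[:, None] * R
    num = Ap + WR @ Bn
    den = An + WR @ Bp
    out = R * np.sqrt(np.maximum(num, eps) / np.maximum(den, eps))
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite entries in row-indicator update")
    return out


def update_C(
    G: np.ndarray,
    R: np.ndarray,
    C: np.ndarray,
    weights: GeneWeights | np.ndarray | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the column indicator matrix (mirror of
    :func:`update_R`, with Dm = X3^T W X4 and F = X4^T W X4)."""
    w = _as_weight_vector(weights, G.shape[0])
    X3 = G - R @ _gram_solve(R, R.T @ G)
    X4 = (_gram_solve(C, (X3 @ C).T)).T
    Dm = X3.T @ (w[:, None] * X4)
    F = X4.T @ (w[:, None] * X4)
    Dp, Dn = _pos_neg(Dm)
    Fp, Fn = _pos_neg(F)
    num = Dp + C @ Fn
    den = Dn + C @ Fp
    out = C * np.sqrt(np.maximum(num, eps) / np.maximum(den, eps))
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite entries in column-indicator update")
    return out


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=1, keepdims=True)
    return M / np.maximum(s, 1e-300)


# ---------------------------------------------------------------------------
# initialisation


def _one_hot(labels: np.ndarray, k: int, jitter: float) -> np.ndarray:
    M = np.full((labels.shape[0], k), jitter)
    M[np.arange(labels.shape[0]), labels] = 1.0
    return _normalize_rows(M)


def initialize_indicators(
    G: np.ndarray,
    k: int,
    d: int,
    method: str = "random",
    random_state: int | np.random.Generator | None = None,
    init_jitter: float = 1e-2,
    kmeans_n_init: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial (R, C).

    ``random`` draws entries uniform(0, 1) and normalises rows; ``kmeans``
    runs k-means on the rows and on the columns of G, one-hot encodes the
    labels and replaces exact zeros by ``init_jitter`` (multiplicative
    updates cannot revive exact zeros).  ``kmeans_n_init`` is passed through
    to k-means; a value of 1 gives a genuinely random single start, which is
    what consensus runs use.
    """
    m, n = G.shape
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, {n}], got {d}")
    rng = np.random.default_rng(random_state)
    if method == "random":
        R = _normalize_rows(rng.uniform(size=(m, k)))
        C = _normalize_rows(rng.uniform(size=(n, d)))
        return R, C
    if method != "kmeans":
        raise ValueError(f"init must be 'random' or 'kmeans', got {method!r}")
    for attempt in range(10):
        seed = int(rng.integers(0, 2**31 - 1))
        rl = (
            KMeans(n_clusters=k, n_init=kmeans_n_init, random_state=seed)
            .fit_predict(G)
            if k > 1
            else np.zeros(m, dtype=int)
        )
        cl = (
            KMeans(n_clusters=d, n_init=kmeans_n_init, random_state=seed + 1)
            .fit_predict(G.T)
            if d > 1
            else np.zeros(n, dtype=int)
        )
        if len(np.unique(rl)) == k and len(np.unique(cl)) == d:
            return _one_hot(rl, k, init_jitter), _one_hot(cl, d, init_jitter)
    raise RuntimeError("k-means produced an empty cluster in 10 attempts")


# ---------------------------------------------------------------------------
# hardening


def _harden(M: np.ndarray) -> np.ndarray:
    """Per-row argmax labels; ties resolved to the smallest cluster index."""
    return np.argmax(M, axis=1)


def _repair_empty(
    labels: np.ndarray,
    n_clusters: int,
    row_residue: np.ndarray,
) -> np.ndarray:
    """Reassign worst-residue items into empty clusters, keeping all clusters
    non-empty.  ``row_residue`` is the per-item weighted residue under the
    current hard partition."""
    labels = labels.copy()
    for c in range(n_clusters):
        if (labels == c).any():
            continue
        counts = np.bincount(labels, minlength=n_clusters)
        movable = counts[labels] > 1
        if not movable.any():
            break
        cand = np.where(movable)[0]
        worst = cand[np.argmax(row_residue[cand])]
        labels[worst] = c
    return labels


# ---------------------------------------------------------------------------
# full fit


@dataclass
class BiClusteringResult:
    """Output of one bi-clustering run."""

    row_labels: np.ndarray
    col_labels: np.ndarray
    R: np.ndarray
    C: np.ndarray
    objective_trace: np.ndarray
    k: int
    d: int
    theta: float
    random_state: int | None
    n_iter: int = 0
    weights: np.ndarray | None = None
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


def fit_biclustering(
    G: np.ndarray,
    k: int,
    d: int,
    weights: GeneWeights | np.ndarray | None = None,
    max_iter: int = 300,
    init: str = "random",
    random_state: int | None = None,
    rtol: float = 1e-8,
    patience: int = 5,
    eps: float = 1e-12,
    init_jitter: float = 1e-2,
    renormalize: bool = True,
    safeguard: bool = True,
    theta: float = 0.0,
    kmeans_n_init: int = 10,
) -> BiClusteringResult:
    """Alternating safeguarded multiplicative updates, then argmax hardening.

    Runs at most ``max_iter`` iterations (one R update and one C update
    each), stopping early when the relative objective decrease stays below
    ``rtol`` for ``patience`` consecutive iterations.  With
    ``safeguard=True`` a half-step is kept only if it does not increase the
    objective, so the recorded trace is non-increasing.  Hard labels are the
    per-row argmax of R and C; clusters emptied by hardening are repaired by
    moving the rows (columns) with the largest weighted residue into them.
    """
    G = np.asarray(G, dtype=float)
    if not np.isfinite(G).all():
        raise ValueError("data matrix contains non-finite values")
    m, n = G.shape
    w = _as_weight_vector(weights, m)
    R, C = initialize_indicators(
        G, k, d, method=init, random_state=random_state,
        init_jitter=init_jitter, kmeans_n_init=kmeans_n_init,
    )
    obj = objective(G, R, C, w)
    trace = [obj]
    stall = 0
    n_iter = 0
    for t in range(max_iter):
        n_iter = t + 1
        R_new = update_R(G, R, C, w, eps=eps)
        if renormalize:
            R_new = _normalize_rows(R_new)
        if safeguard:
            o = objective(G, R_new, C, w)
            if o <= obj:
                R, obj = R_new, o
        else:
            R = R_new
            obj = objective(G, R, C, w)
        C_new = update_C(G, R, C, w, eps=eps)
        if renormalize:
            C_new = _normalize_rows(C_new)
        if safeguard:
            o = objective(G, R, C_new, w)
            if o <= obj:
                C, obj = C_new, o
        else:
            C = C_new
            obj = objective(G, R, C, w)
        trace.append(obj)
        rel = (trace[-2] - trace[-1]) / max(abs(trace[-2]), 1e-300)
        stall = stall + 1 if rel < rtol else 0
        if stall >= patience:
            break
    row_labels = _harden(R)
    col_labels = _harden(C)
    # per-item weighted residues under the hard partition, for empty-cluster repair
    Rh = _one_hot(row_labels, k, 0.0)
    Ch = _one_hot(col_labels, d, 0.0)
    H = residue_decomposition(G, np.where(Rh > 0, 1.0, 1e-12), np.where(Ch > 0, 1.0, 1e-12))["residual"]
    row_res = (w[:, None] * H * H).sum(axis=1)
    col_res = (w[:, None] * H * H).sum(axis=0)
    row_labels = _repair_empty(row_labels, k, row_res)
    col_labels = _repair_empty(col_labels, d, col_res)
    return BiClusteringResult(
        row_labels=row_labels,
        col_labels=col_labels,
        R=R,
        C=C,
        objective_trace=np.asarray(trace),
        k=k,
        d=d,
        theta=theta,
        random_state=random_state,
        n_iter=n_iter,
        weights=w,
    )


# ---------------------------------------------------------------------------
# bi-cluster extraction


def extract_biclusters(
    row_labels: Sequence[int] | BiClusteringResult,
    col_labels: Sequence[int] | None = None,
    gene_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[BiCluster]:
    """All non-empty (row cluster x column cluster) blocks of the checkerboard.

    Blocks are returned in (row cluster, column cluster) index order and use
    identifiers when given, integer indices otherwise.  Their union covers
    every matrix cell exactly once.
    """
    if isinstance(row_labels, BiClusteringResult):
        res = row_labels
        col_labels = res.col_labels
        gene_ids = gene_ids or (res.gene_ids or None)
        sample_ids = sample_ids or (res.sample_ids or None)
        row_labels = res.row_labels
    rl = np.asarray(row_labels)
    cl = np.asarray(col_labels)
    genes = list(gene_ids) if gene_ids is not None else list(range(rl.shape[0]))
    samples = list(sample_ids) if sample_ids is not None else list(range(cl.shape[0]))
    out: list[BiCluster] = []
    for a in np.unique(rl):
        gset = frozenset(genes[i] for i in np.where(rl == a)[0])
        for b in np.unique(cl):
            sset = frozenset(samples[j] for j in np.where(cl == b)[0])
            if gset and sset:
                out.append(BiCluster(gset, sset))
    return out


def block_mean_squared_residue(
    G: np.ndarray, rows: Sequence[int], cols: Sequence[int]
) -> float:
    """Mean squared residue of a single block (explicit group means)."""
    S = G[np.ix_(list(rows), list(cols))]
    H = S - S.mean(axis=1, keepdims=True) - S.mean(axis=0, keepdims=True) + S.mean()
    return float((H * H).mean())


def top_biclusters(
    G: np.ndarray,
    row_labels: Sequence[int],
    col_labels: Sequence[int],
    n: int,
    gene_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[BiCluster]:
    """The ``n`` most coherent checkerboard blocks (smallest mean squared
    residue).  Useful when the number of sought bi-clusters is smaller than
    k*d, e.g. on implant benchmarks where most blocks are background."""
    rl = np.asarray(row_labels)
    cl = np.asarray(col_labels)
    genes = list(gene_ids) if gene_ids is not None else list(range(rl.shape[0]))
    samples = list(sample_ids) if sample_ids is not None else list(range(cl.shape[0]))
    scored = []
    for a in np.unique(rl):
        ri = np.where(rl == a)[0]
        for b in np.unique(cl):
            ci = np.where(cl == b)[0]
            if ri.size == 0 or ci.size == 0:
                continue
            score = block_mean_squared_residue(G, ri, ci)
            bc = BiCluster(
                frozenset(genes[i] for i in ri), frozenset(samples[j] for j in ci)
            )
            scored.append((score, len(scored), bc))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [bc for _, _, bc in scored[:n]]


# ---------------------------------------------------------------------------
# estimator


class NetBC(BiclusterMixin, BaseEstimator):
    """Network-aided checkerboard bi-clustering estimator.

    Partitions genes (rows) into ``n_row_clusters`` and samples (columns)
    into ``n_col_clusters`` by minimising the weighted sum-squared residue
    with alternating multiplicative updates.  Per-gene weights blend
    expression variability with a gene-interaction network through the
    GeneRank parameter ``theta``.

    Parameters
    ----------
    n_row_clusters, n_col_clusters : int
        Number of gene clusters k and sample clusters d.
    theta : float, default 0.0
        GeneRank damping; 0 weights genes by expression variation alone,
        values towards 1 weight by network connectivity.  Requires
        ``network`` when positive.
    network : GeneNetwork, optional
        Interaction network aligned to the gene order of the fitted data.
    weights : array-like, GeneWeights, or "uniform", optional
        Explicit per-gene weights; overrides ``theta``/``network``.
    max_iter : int, default 300
        Maximum alternating iterations.
    init : {"random", "kmeans"}, default "random"
        Indicator initialisation.  k-means anchors the iteration near hard
        assignments and is recommended for cluster recovery.
    kmeans_n_init : int, default 10
        Restarts for the k-means initialisation.
    rtol, patience : float, int
        Early stopping: relative objective decrease below ``rtol`` for
        ``patience`` consecutive iterations.
    eps : float, default 1e-12
        Floor for numerators and denominators of the multiplicative updates.
    init_jitter : float, default 1e-2
        Replacement for exact zeros in one-hot initial indicators.
    renormalize : bool, default True
        Renormalise indicator rows to sum to one after each update.
    safeguard : bool, default True
        Accept a half-step only if it does not increase the objective.
    deviation : {"mad", "std", "range"}, default "mad"
        Expression-variation score used when weights are computed.
    random_state : int, optional
        Seed for initialisation.

    Attributes
    ----------
    row_labels_, column_labels_ : ndarray
        Hard cluster labels for genes and samples.
    R_, C_ : ndarray
        Final soft indicator matrices.
    objective_trace_ : ndarray
        Objective value per iteration (non-increasing under the safeguard).
    weights_ : ndarray
        Per-gene weights used in the fit.
    biclusters_ : (rows, columns)
        Boolean block membership matrices (scikit-learn bicluster API).

    Examples
    --------
    >>> from netbc.simulate import make_checkerboard
    >>> expr, rows, cols = make_checkerboard(60, 30, 3, 2, seed=0)
    >>> model = NetBC(3, 2, init="kmeans", random_state=0).fit(expr.values)
    >>> model.row_labels_.shape, model.column_labels_.shape
    ((60,), (30,))
    """

    def __init__(
        self,
        n_row_clusters: int = 3,
        n_col_clusters: int = 2,
        *,
        theta: float = 0.0,
        network=None,
        weights=None,
        max_iter: int = 300,
        init: str = "random",
        kmeans_n_init: int = 10,
        rtol: float = 1e-8,
        patience: int = 5,
        eps: float = 1e-12,
        init_jitter: float = 1e-2,
        renormalize: bool = True,
        safeguard: bool = True,
        deviation: str = "mad",
        random_state: int | None = None,
    ):
        self.n_row_clusters = n_row_clusters
        self.n_col_clusters = n_col_clusters
        self.theta = theta
        self.network = network
        self.weights = weights
        self.max_iter = max_iter
        self.init = init
        self.kmeans_n_init = kmeans_n_init
        self.rtol = rtol
        self.patience = patience
        self.eps = eps
        self.init_jitter = init_jitter
        self.renormalize = renormalize
        self.safeguard = safeguard
        self.deviation = deviation
        self.random_state = random_state

    def _resolve_weights(self, G: np.ndarray) -> np.ndarray:
        m = G.shape[0]
        if isinstance(self.weights, str):
            if self.weights != "uniform":
                raise ValueError("weights string option must be 'uniform'")
            return np.ones(m)
        if self.weights is not None:
            return _as_weight_vector(
                self.weights.w if isinstance(self.weights, GeneWeights) else self.weights,
                m,
            )
        gw = compute_weights(
            G, network=self.network, theta=self.theta, deviation=self.deviation
        )
        return gw.w

    def fit(self, X, y=None):
        """Fit the checkerboard bi-clustering to a genes x samples matrix.

        ``X`` may be an ndarray, a pandas DataFrame or an
        :class:`~netbc.io.ExpressionMatrix`.
        """
        gene_ids: list[str] = []
        sample_ids: list[str] = []
        if isinstance(X, ExpressionMatrix):
            gene_ids, sample_ids = X.gene_ids, X.sample_ids
            G = X.values
        elif hasattr(X, "to_numpy") and hasattr(X, "index"):
            gene_ids = [str(g) for g in X.index]
            sample_ids = [str(s) for s in X.columns]
            G = X.to_numpy(dtype=float)
        else:
            G = np.asarray(X, dtype=float)
        if G.ndim != 2:
            raise ValueError("expected a 2-d genes x samples matrix")
        w = self._resolve_weights(G)
        result = fit_biclustering(
            G,
            self.n_row_clusters,
            self.n_col_clusters,
            weights=w,
            max_iter=self.max_iter,
            init=self.init,
            random_state=self.random_state,
            rtol=self.rtol,
            patience=self.patience,
            eps=self.eps,
            init_jitter=self.init_jitter,
            renormalize=self.renormalize,
            safeguard=self.safeguard,
            theta=self.theta,
            kmeans_n_init=self.kmeans_n_init,
        )
        result.gene_ids = gene_ids
        result.sample_ids = sample_ids
        self.result_ = result
        self.row_labels_ = result.row_labels
        self.column_labels_ = result.col_labels
        self.R_ = result.R
        self.C_ = result.C
        self.objective_trace_ = result.objective_trace
        self.weights_ = w
        self.n_iter_ = result.n_iter
        # scikit-learn bicluster API: one (rows, columns) pair per block
        k, d = self.n_row_clusters, self.n_col_clusters
        rows = np.zeros((k * d, G.shape[0]), dtype=bool)
        cols = np.zeros((k * d, G.shape[1]), dtype=bool)
        for a in range(k):
            for b in range(d):
                rows[a * d + b] = result.row_labels == a
                cols[a * d + b] = result.col_labels == b
        self.rows_ = rows
        self.columns_ = cols
        return self

    def get_biclusters_(self) -> list[BiCluster]:
        """Checkerboard blocks as (gene set, sample set) pairs."""
        check_is_fitted(self, "result_")
        return extract_biclusters(self.result_)
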