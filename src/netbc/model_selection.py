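"""Choosing the number of gene and sample clusters by consensus stability.

For a candidate (k, d) the bi-clustering is run repeatedly with different
random initialisations; each run yields a gene co-assignment matrix
(M_ij = 1 iff genes i and j share a cluster) and a sample co-assignment
matrix.  Their averages over runs are the consensus matrices.  A suitable
(k, d) produces near-binary consensus: the cophenetic correlation
coefficient — the Pearson correlation between the consensus distance
1 - M and the dendrogram distances of an average-linkage clustering of it —
approaches 1.  The selected (k, d) maximises the mean of the gene and
sample coefficients.

Consensus is taken over initialisations, not over data resamples.  Each
run uses a single-start k-means initialisation (``kmeans_n_init=1``): a
multi-start k-means is nearly deterministic, which would make merged or
split partitions spuriously stable; a purely random soft initialisation
suffers from the mixing degeneracy of the continuous relaxation (see
:mod:`netbc.biclustering`).  A single random k-means start varies the
merge/split choices at a wrong (k, d) while reliably recovering a true,
well-separated partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .biclustering import fit_biclustering
from .io import ExpressionMatrix
from .weighting import GeneWeights

__all__ = [
    "coassignment",
    "consensus",
    "cophenetic_coefficient",
    "select_k_d",
    "SelectionResult",
]


def coassignment(labels) -> np.ndarray:
    """0/1 symmetric matrix with M_ij = 1 iff labels_i == labels_j."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.shape[0] < 2:
        raise ValueError("labels must be a 1-d vector of length >= 2")
    return (labels[:, None] == labels[None, :]).astype(float)


def _values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def consensus(
    X,
    k: int,
    d: int,
    weights: GeneWeights | np.ndarray | None = None,
    n_runs: int = 20,
    random_state: int | None = None,
    max_iter: int = 150,
    kmeans_n_init: int = 1,
    **fit_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Average gene and sample co-assignment matrices over ``n_runs`` fits.

    Runs use seeds random_state, random_state + 1, ...; a failed run is
    skipped with a warning, and fewer than two successes is an error.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    G = _values(X)
    base = 0 if random_state is None else int(random_state)
    Mg = np.zeros((G.shape[0], G.shape[0]))
    Ms = np.zeros((G.shape[1], G.shape[1]))
    ok = 0
    for r in range(n_runs):
        try:
            res = fit_biclustering(
                G, k, d, weights=weights, init="kmeans",
                kmeans_n_init=kmeans_n_init, max_iter=max_iter,
                random_state=(base + r) % (2**31 - 1), **fit_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - any run failure is skipped
            warnings.warn(f"consensus run {r} failed: {exc}", RuntimeWarning, stacklevel=2)
            continue
        Mg += coassignment(res.row_labels)
        Ms += coassignment(res.col_labels)
        ok += 1
    if ok < 2:
        raise RuntimeError(f"only {ok} of {n_runs} consensus runs succeeded")
    return Mg / ok, Ms / ok


def cophenetic_coefficient(M: np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    Builds the distance matrix 1 - M, clusters it by average linkage and
    returns the Pearson correlation between the observed and the cophenetic
    (dendrogram) distances.  A zero-variance distance vector (perfectly
    stable consensus) returns 1 by convention.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 3:
        raise ValueError("consensus matrix must be square with size >= 3")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    y = squareform(D, checks=False)
    if np.std(y) == 0.0:
        warnings.warn(
            "consensus distances have zero variance; cophenetic coefficient "
            "set to 1 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    Z = linkage(y, method="average")
    c, _ = cophenet(Z, y)
    if np.isnan(c):
        warnings.warn(
            "degenerate cophenetic distances; coefficient set to 1 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return float(c)


@dataclass
class SelectionResult:
    k: int
    d: int
    grid: pd.DataFrame  # columns: k, d, rho_genes, rho_samples, combined


def select_k_d(
    X,
    k_values,
    d_values,
    weights: GeneWeights | np.ndarray | None = None,
    n_runs: int = 20,
    random_state: int | None = None,
    max_iter: int = 150,
    **fit_kwargs,
) -> SelectionResult:
    """Evaluate consensus stability on a (k, d) grid and return the argmax.

    Exact ties (within 1e-12) are resolved towards the largest k, then the
    largest d: a coarse merge of well-separated clusters is reproducible by
    construction, so equal stability carries no evidence for the smaller
    model, while the larger one explains more structure at the same
    reproducibility.
    """
    k_values = sorted(set(int(k) for k in k_values))
    d_values = sorted(set(int(d) for d in d_values))
    if not k_values or not d_values:
        raise ValueError("k_values and d_values must be non-empty")
    base = 0 if random_state is None else int(random_state)
    rows = []
    for idx_k, k in enumerate(k_values):
        for idx_d, d in enumerate(d_values):
            cell_seed = (base + 10_000 * (idx_k * len(d_values) + idx_d)) % (2**31 - 1)
            Mg, Ms = consensus(
                X, k, d, weights=weights, n_runs=n_runs,
                random_state=cell_seed, max_iter=max_iter, **fit_kwargs,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rho_g = cophenetic_coefficient(Mg)
                rho_s = cophenetic_coefficient(Ms)
            combined = (rho_g + rho_s) / 2.0
            rows.append(
                {"k": k, "d": d, "rho_genes": rho_g, "rho_samples": rho_s,
                 "combined": combined}
            )
    grid = pd.DataFrame(rows)
    top = grid["combined"].max()
    tied = grid[grid["combined"] >= top - 1e-12]
    winner = tied.sort_values(["k", "d"], ascending=False).iloc[0]
    return SelectionResult(k=int(winner["k"]), d=int(winner["d"]), grid=grid)
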