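"""Desk-scale benchmark protocols for the bi-clustering pipeline.

Each function runs a complete, self-contained experiment at a fixed design
and returns the measured quantities.  The designs are chosen so a full run
of every protocol takes a few minutes on one CPU:

* residue-oracle agreement on random instances (m <= 50, n <= 20),
* objective-trace monotonicity across the five implant pattern types,
* GeneRank solver consistency on 200-gene networks,
* noiseless checkerboard recovery (types i-iv),
* implant relevance/recovery at low noise,
* pair-counting metric agreement with exhaustive enumeration,
* consensus model selection on a symmetric checkerboard,
* network-weighting benefit under noisy genes, and its robustness to
  random edge rewiring.

All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import itertools

import numpy as np

from .biclustering import (
    fit_biclustering,
    objective,
    top_biclusters,
)
from .metrics import (
    PairCounts,
    f1_measure,
    pair_counts,
    rand_index,
    rand_score,
    recovery,
    relevance,
)
from .model_selection import select_k_d
from .simulate import (
    PATTERN_KINDS,
    generate_structured_network,
    inject_noisy_genes,
    make_checkerboard,
    make_implanted_dataset,
    perturb_network,
)
from .weighting import compute_weights, expression_deviation, generank_direct, generank_iterative

__all__ = [
    "residue_oracle_error",
    "monotonicity_worst_step",
    "generank_consistency",
    "checkerboard_recovery",
    "implant_recovery",
    "metric_oracle_agreement",
    "model_selection_hit_rate",
    "weighting_benefit",
    "rewiring_sensitivity",
]

RECOVERABLE_KINDS = PATTERN_KINDS[:4]  # constant .. additive


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    M = np.zeros((labels.shape[0], k))
    M[np.arange(labels.shape[0]), labels] = 1.0
    return M


def _random_partition(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    while True:
        lab = rng.integers(0, k, size=n)
        if len(np.unique(lab)) == k:
            return lab


def _blockwise_ssr(G, rl, cl, w) -> float:
    total = 0.0
    for a in np.unique(rl):
        I = np.where(rl == a)[0]
        for b in np.unique(cl):
            J = np.where(cl == b)[0]
            S = G[np.ix_(I, J)]
            H = (
                S
                - S.mean(axis=1, keepdims=True)
                - S.mean(axis=0, keepdims=True)
                + S.mean()
            )
            total += float((w[I, None] * H * H).sum())
    return total


def residue_oracle_error(n_instances: int = 100, seed: int = 0) -> float:
    """Max relative disagreement between the matrix-form objective and the
    explicit blockwise sum-squared residue on random hard partitions."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(8, 51))
        n = int(rng.integers(6, 21))
        k = int(rng.integers(2, 6))
        d = int(rng.integers(2, 5))
        G = rng.standard_normal((m, n))
        rl = _random_partition(rng, m, k)
        cl = _random_partition(rng, n, d)
        w = rng.uniform(0.2, 2.0, m)
        got = objective(G, _one_hot(rl, k), _one_hot(cl, d), w)
        want = _blockwise_ssr(G, rl, cl, w)
        worst = max(worst, abs(got - want) / max(abs(want), 1e-300))
    return worst


def monotonicity_worst_step(
    n_seeds: int = 10, sigma: float = 0.1, max_iter: int = 150, seed: int = 0
) -> float:
    """Largest per-step objective increase over fits on all five implant
    pattern types with random and k-means initialisation (0 when the trace
    is perfectly non-increasing)."""
    worst = -np.inf
    for kind_i, kind in enumerate(PATTERN_KINDS):
        for s in range(n_seeds):
            expr, _, _ = make_implanted_dataset(
                kind=kind, sigma=sigma, seed=seed + 1000 * kind_i + s
            )
            for init in ("random", "kmeans"):
                res = fit_biclustering(
                    expr.values, 4, 4,
                    weights=compute_weights(expr).w,
                    init=init, random_state=seed + 7 * s, max_iter=max_iter,
                )
                worst = max(worst, float(np.max(np.diff(res.objective_trace))))
    return worst


def generank_consistency(
    m: int = 200, thetas=(0.1, 0.5, 0.85), seed: int = 0
) -> dict[str, float]:
    """Max-norm gap between the direct solve and the fixed-point iteration,
    plus the theta = 0 deviation from the raw expression scores."""
    rng = np.random.default_rng(seed)
    net = generate_structured_network(
        m, rng.choice(m, m // 5, replace=False), p_hub=0.1, p_background=0.02,
        seed=seed + 1,
    )
    e = rng.uniform(0.0, 2.0, m)
    gap = 0.0
    for theta in thetas:
        wd = generank_direct(net, e, theta).w
        wi = generank_iterative(net, e, theta, tol=1e-10).w
        gap = max(gap, float(np.max(np.abs(wd - wi))))
    w0 = generank_direct(net, e, 0.0).w
    theta0_gap = float(np.max(np.abs(w0 - e / e.mean())))
    return {"solver_gap": gap, "theta0_gap": theta0_gap}


def checkerboard_recovery(
    n_seeds: int = 10, m: int = 60, n: int = 30, k: int = 3, d: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Noiseless full-checkerboard recovery for pattern types i-iv.

    Returns the largest objective at the truth partition and the fraction
    of fits (k-means init) recovering both label vectors exactly (RI = 1).
    """
    worst_obj = 0.0
    perfect = 0
    total = 0
    for kind_i, kind in enumerate(RECOVERABLE_KINDS):
        for s in range(n_seeds):
            expr, rl, cl = make_checkerboard(
                m, n, k, d, kind=kind, sigma=0.0, seed=seed + 999 * kind_i + s
            )
            w = compute_weights(expr).w
            worst_obj = max(
                worst_obj, objective(expr.values, _one_hot(rl, k), _one_hot(cl, d), w)
            )
            res = fit_biclustering(
                expr.values, k, d, weights=w, init="kmeans",
                random_state=seed + 13 * s,
            )
            total += 1
            perfect += int(
                rand_score(rl, res.row_labels) == 1.0
                and rand_score(cl, res.col_labels) == 1.0
            )
    return {"truth_objective_max": worst_obj, "perfect_fraction": perfect / total}


def implant_recovery(
    n_seeds: int = 10, sigma: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Relevance/recovery on the implant benchmark (100 x 50 background,
    three 15 x 8 implants), pattern types i-iv.

    The fit uses one extra row and column cluster for the background and the
    three most coherent blocks are reported as the discovered bi-clusters.
    """
    rels, recs = [], []
    for kind_i, kind in enumerate(RECOVERABLE_KINDS):
        for s in range(n_seeds):
            expr, truth, _ = make_implanted_dataset(
                m=100, n=50, n_biclusters=3, bicluster_shape=(15, 8),
                kind=kind, sigma=sigma, seed=seed + 499 * kind_i + s,
            )
            res = fit_biclustering(
                expr.values, 4, 4, weights=compute_weights(expr).w,
                init="random", random_state=seed + 17 * s,
            )
            disc = top_biclusters(
                expr.values, res.row_labels, res.col_labels, 3,
                gene_ids=expr.gene_ids, sample_ids=expr.sample_ids,
            )
            rels.append(relevance(disc, truth))
            recs.append(recovery(disc, truth))
    return {"mean_relevance": float(np.mean(rels)), "mean_recovery": float(np.mean(recs))}


def _brute_force_counts(truth, pred) -> PairCounts:
    n = len(truth)
    np1 = np2 = np3 = np4 = 0
    for i, j in itertools.combinations(range(n), 2):
        st = truth[i] == truth[j]
        sp = pred[i] == pred[j]
        if st and sp:
            np1 += 1
        elif st:
            np2 += 1
        elif sp:
            np3 += 1
        else:
            np4 += 1
    return PairCounts(np1, np2, np3, np4)


def metric_oracle_agreement(seed: int = 0, n_random: int = 500) -> float:
    """Fraction of label-vector pairs on which RI and F1 agree exactly with
    brute-force pair enumeration (exhaustive at length 4 over 3 clusters,
    random at lengths 5-8)."""
    pairs = []
    for t in itertools.product(range(3), repeat=4):
        for p in itertools.product(range(3), repeat=4):
            pairs.append((t, p))
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        n = int(rng.integers(5, 9))
        pairs.append(
            (tuple(rng.integers(0, 3, n)), tuple(rng.integers(0, 3, n)))
        )
    agree = 0
    for t, p in pairs:
        c = pair_counts(t, p)
        b = _brute_force_counts(t, p)
        same = (
            c == b
            and rand_index(c) == rand_index(b)
            and f1_measure(c) == f1_measure(b)
        )
        agree += int(same)
    return agree / len(pairs)


def _symmetric_block_means(scale: float = 1.5) -> np.ndarray:
    """Row-group means at the vertices of an equilateral triangle in the
    2-dim block-mean space: no privileged merge when k is forced below 3."""
    return scale * np.array(
        [[1.0, 0.0], [-0.5, np.sqrt(3) / 2], [-0.5, -np.sqrt(3) / 2]]
    )


def model_selection_hit_rate(
    n_reps: int = 5, n_runs: int = 10, seed: int = 0
) -> float:
    """Fraction of repetitions in which consensus stability selects the true
    (k, d) = (3, 2) on a symmetric constant-block checkerboard, searching
    k in 2..4 and d in 2..3."""
    hits = 0
    mu = _symmetric_block_means()
    for rep in range(n_reps):
        expr, _, _ = make_checkerboard(
            60, 30, 3, 2, kind="constant", sigma=0.1,
            seed=seed + 211 * rep, block_means=mu,
        )
        w = compute_weights(expr).w
        sel = select_k_d(
            expr, [2, 3, 4], [2, 3], weights=w, n_runs=n_runs,
            random_state=seed + 97 * rep, max_iter=100,
        )
        hits += int((sel.k, sel.d) == (3, 2))
    return hits / n_reps


def _noisy_gene_experiment(
    seed: int, theta: float, rewire_fraction: float = 0.0
) -> float:
    """One run of the noisy-gene protocol; returns the sample Rand index.

    Checkerboard data (100 genes x 40 samples, 3 x 3 constant blocks,
    sigma = 0.1); 30 % of genes are non-hubs in a structured network, get
    the lowest network-aware weights and are replaced by uniform noise.
    The fit then uses weights at the requested theta computed on the noisy
    data and the (optionally rewired) network.
    """
    rng = np.random.default_rng(seed)
    m, n, k, d = 100, 40, 3, 3
    n_noisy = 30
    expr, _, cl = make_checkerboard(
        m, n, k, d, kind="constant", sigma=0.1, seed=seed
    )
    informative = rng.choice(m, m - n_noisy, replace=False)
    net = generate_structured_network(
        m, informative, p_hub=0.2, p_background=0.02,
        seed=seed + 1, gene_ids=expr.gene_ids,
    )
    # tag the lowest network-aware weights as noisy and destroy those genes
    w_clean = compute_weights(expr, network=net, theta=0.85).w
    noisy_expr, _ = inject_noisy_genes(expr, w_clean, n_noisy, seed=seed + 2)
    if rewire_fraction > 0:
        n_rewire = int(round(rewire_fraction * net.n_edges))
        net = perturb_network(net, n_rewire=n_rewire, seed=seed + 3)
    if theta == 0.0:
        w = compute_weights(noisy_expr).w
    else:
        w = compute_weights(noisy_expr, network=net, theta=theta).w
    res = fit_biclustering(
        noisy_expr.values, k + 1, d, weights=w, init="kmeans",
        random_state=seed + 4, max_iter=150,
    )
    return rand_score(cl, res.col_labels)


def weighting_benefit(n_seeds: int = 10, seed: int = 0) -> dict[str, float]:
    """Mean sample Rand index with network-aware weights (theta = 0.85)
    versus expression-only weights (theta = 0) under 30 % noisy genes."""
    ri0 = [_noisy_gene_experiment(seed + s, 0.0) for s in range(n_seeds)]
    ri85 = [_noisy_gene_experiment(seed + s, 0.85) for s in range(n_seeds)]
    return {
        "ri_theta0": float(np.mean(ri0)),
        "ri_theta85": float(np.mean(ri85)),
        "benefit": float(np.mean(ri85) - np.mean(ri0)),
    }


def rewiring_sensitivity(
    n_seeds: int = 10, rewire_fraction: float = 0.1, seed: int = 0
) -> dict[str, float]:
    """Absolute change of the mean theta = 0.85 sample Rand index when 10 %
    of network edges are randomly rewired."""
    base = [_noisy_gene_experiment(seed + s, 0.85) for s in range(n_seeds)]
    rewired = [
        _noisy_gene_experiment(seed + s, 0.85, rewire_fraction)
        for s in range(n_seeds)
    ]
    return {
        "ri_intact": float(np.mean(base)),
        "ri_rewired": float(np.mean(rewired)),
        "abs_change": float(abs(np.mean(rewired) - np.mean(base))),
    }
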