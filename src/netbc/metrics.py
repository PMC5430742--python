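"""Clustering and bi-clustering quality scores.

Partition agreement is scored by pair counting: over all unordered item
pairs, np1 counts pairs co-clustered in both partitions, np2 pairs
co-clustered only in the reference, np3 only in the prediction, and np4 in
neither.  The Rand index is (np1 + np4) / total, precision np1/(np1+np3),
recall np1/(np1+np2), and F1 their harmonic mean.

Bi-cluster sets are scored by best-match Jaccard over gene sets: the
relevance of a discovered set E' against a reference set E is

    S_G(E', E) = (1/|E'|) * sum_{(G',S') in E'} max_{(G,S) in E} |G' & G| / |G' | G|

and recovery is the same score with the arguments swapped.  Sample sets are
carried in the tuples but do not enter the score; an optional both-dimension
variant multiplies gene-set and sample-set Jaccard.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "BiCluster",
    "PairCounts",
    "pair_counts",
    "rand_index",
    "rand_score",
    "f1_measure",
    "relevance",
    "recovery",
]


class BiCluster(NamedTuple):
    """A gene set / sample set pair (identifiers or indices)."""

    genes: frozenset
    samples: frozenset


class PairCounts(NamedTuple):
    """Unordered-pair agreement counts between two partitions."""

    np1: int  # same cluster in both
    np2: int  # same in reference, different in prediction
    np3: int  # different in reference, same in prediction
    np4: int  # different in both

    @property
    def total(self) -> int:
        return self.np1 + self.np2 + self.np3 + self.np4


def pair_counts(
    truth: Sequence[int], pred: Sequence[int]
) -> PairCounts:
    """Count unordered item pairs by co-clustering status in two partitions."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    n = truth.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    # contingency table; pair counts follow from within-cell/row/column sums
    cont = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ti, pi), 1)
    same_both = int((cont * (cont - 1) // 2).sum())
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    same_truth = int((a * (a - 1) // 2).sum())
    same_pred = int((b * (b - 1) // 2).sum())
    total = n * (n - 1) // 2
    np1 = same_both
    np2 = same_truth - same_both
    np3 = same_pred - same_both
    np4 = total - np1 - np2 - np3
    return PairCounts(np1, np2, np3, np4)


def rand_index(counts: PairCounts) -> float:
    """(np1 + np4) / all pairs, in [0, 1]."""
    return (counts.np1 + counts.np4) / counts.total


def rand_score(truth: Sequence[int], pred: Sequence[int]) -> float:
    """Rand index directly from two label vectors."""
    return rand_index(pair_counts(truth, pred))


def f1_measure(counts: PairCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) from pair counts; 0 on empty denominators."""
    pr = counts.np1 / (counts.np1 + counts.np3) if counts.np1 + counts.np3 else 0.0
    re = counts.np1 / (counts.np1 + counts.np2) if counts.np1 + counts.np2 else 0.0
    f1 = 2.0 * pr * re / (pr + re) if pr + re else 0.0
    return pr, re, f1


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _match_score(bc: BiCluster, other: BiCluster, dimensions: str) -> float:
    g = _jaccard(bc.genes, other.genes)
    if dimensions == "genes":
        return g
    return g * _jaccard(bc.samples, other.samples)


def relevance(
    discovered: Iterable[BiCluster],
    truth: Iterable[BiCluster],
    dimensions: str = "genes",
) -> float:
    """Average best-match Jaccard of discovered gene sets against the truth.

    ``dimensions="genes"`` (default) scores gene sets only; ``"both"``
    multiplies gene-set and sample-set Jaccard.
    """
    if dimensions not in ("genes", "both"):
        raise ValueError("dimensions must be 'genes' or 'both'")
    discovered = list(discovered)
    truth = list(truth)
    if not discovered:
        raise ValueError("discovered bi-cluster set is empty")
    if not truth:
        raise ValueError("reference bi-cluster set is empty")
    return float(
        np.mean(
            [max(_match_score(d, t, dimensions) for t in truth) for d in discovered]
        )
    )


def recovery(
    discovered: Iterable[BiCluster],
    truth: Iterable[BiCluster],
    dimensions: str = "genes",
) -> float:
    """How well the truth is covered: relevance with arguments swapped."""
    return relevance(truth, discovered, dimensions=dimensions)
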