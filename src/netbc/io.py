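"""Reading and writing expression matrices, interaction networks and results.

File dialects are deliberately narrow: expression data is a tab-separated
matrix with a header row of sample identifiers and gene identifiers in the
first column; networks are two-column tab-separated edge lists.  Gene
identifiers are matched by exact string equality after whitespace stripping;
no alias resolution is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneNetwork",
    "ExpressionFormatError",
    "NetworkFormatError",
    "read_expression",
    "write_expression",
    "read_network",
    "align_network",
    "write_labels",
    "read_labels",
    "write_biclusters_json",
    "write_objective_trace",
]


class ExpressionFormatError(ValueError):
    """Raised when an expression file violates the expected dialect."""


class NetworkFormatError(ValueError):
    """Raised when a network edge-list file is malformed."""


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with identifier metadata.

    Attributes
    ----------
    values : ndarray of shape (m, n)
        Expression values, typically log-scale.  Must be finite.
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ExpressionFormatError(
                f"expression matrix must be at least 2x2, got {m}x{n}"
            )
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ExpressionFormatError("identifier count does not match matrix shape")
        if len(set(self.gene_ids)) != m:
            dup = _first_duplicate(self.gene_ids)
            raise ExpressionFormatError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise ExpressionFormatError(f"duplicate sample identifier: {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionFormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class GeneNetwork:
    """Gene interaction network aligned to an expression gene order.

    The adjacency matrix ``P`` is binary with zero diagonal; for an
    undirected network it is symmetric.  ``degrees`` follows the column-sum
    convention deg_j = sum_i P_ij, i.e. the number of genes interacting
    *with* gene j.
    """

    adjacency: sp.csr_matrix
    directed: bool
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise NetworkFormatError("adjacency must be square")
        A.setdiag(0)
        A.eliminate_zeros()
        data = A.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise NetworkFormatError("adjacency entries must be 0/1")
        if not self.directed:
            if (A != A.T).nnz != 0:
                raise NetworkFormatError("undirected network must be symmetric")
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Column sums deg_j = sum_i P_ij."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    @property
    def n_edges(self) -> int:
        nnz = self.adjacency.nnz
        return nnz if self.directed else nnz // 2


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate found")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, column 1 = gene ids).

    Raises
    ------
    ExpressionFormatError
        On duplicate identifiers, non-numeric or missing cells, or fewer
        than two rows or columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ExpressionFormatError(
            f"{path}: expression matrix must have at least 2 genes and 2 samples, "
            f"got {df.shape[0]}x{df.shape[1]}"
        )
    gene_ids = [str(g).strip() for g in df.index]
    sample_ids = [str(s).strip() for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("missing")
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ExpressionFormatError(
                    f"{path}: non-numeric or missing value at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}: {cell!r}"
                ) from exc
    return ExpressionMatrix(values, gene_ids, sample_ids)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV; round-trips bit-identically."""
    expr.to_frame().to_csv(path, sep="\t")


def read_network(path: str | Path, directed: bool = False) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list.

    Comment lines starting with ``#`` are skipped.  Duplicate edges and
    self-loops are removed, with counts logged.  For undirected input,
    (a, b) and (b, a) are the same edge.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise NetworkFormatError(
                    f"{path}: malformed edge at line {lineno}: {line!r}"
                )
            a, b = parts
            if a == b:
                n_self += 1
                continue
            key = (a, b) if directed else (min(a, b), max(a, b))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append((a, b))
    if n_self:
        logger.info("read_network: dropped %d self-loop(s) from %s", n_self, path)
    if n_dup:
        logger.info("read_network: dropped %d duplicate edge(s) from %s", n_dup, path)
    return edges


def align_network(
    edges: Sequence[tuple[str, str]],
    expr: ExpressionMatrix,
    directed: bool = False,
) -> GeneNetwork:
    """Build an m x m adjacency aligned to the expression gene order.

    Edges with an endpoint absent from the expression matrix are dropped
    (count logged); genes absent from the edge list get degree zero.
    """
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    m = expr.n_genes
    rows: list[int] = []
    cols: list[int] = []
    n_dropped = 0
    for a, b in edges:
        a, b = str(a).strip(), str(b).strip()
        ia = index.get(a)
        ib = index.get(b)
        if ia is None or ib is None or ia == ib:
            n_dropped += 1
            continue
        rows.append(ia)
        cols.append(ib)
        if not directed:
            rows.append(ib)
            cols.append(ia)
    if n_dropped:
        logger.info("align_network: dropped %d edge(s) with unknown endpoints", n_dropped)
    data = np.ones(len(rows), dtype=float)
    A = sp.csr_matrix((data, (rows, cols)), shape=(m, m))
    A.data[:] = 1.0  # collapse duplicate entries to binary
    if A.nnz == 0:
        logger.warning("align_network: no edges overlap the expression genes")
    return GeneNetwork(A, directed=directed, gene_ids=list(expr.gene_ids))


def write_labels(ids: Sequence[str], labels: Sequence[int], path: str | Path) -> None:
    pd.DataFrame({"id": list(ids), "cluster": list(map(int, labels))}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cluster": int})
    return list(df["id"]), df["cluster"].to_numpy()


def write_biclusters_json(biclusters, path: str | Path) -> None:
    """Write a bi-cluster set as JSON: [{"genes": [...], "samples": [...]}]."""
    payload = [
        {"genes": sorted(map(str, bc.genes)), "samples": sorted(map(str, bc.samples))}
        for bc in biclusters
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_biclusters_json(path: str | Path):
    from .metrics import BiCluster

    with open(path) as fh:
        payload = json.load(fh)
    return [
        BiCluster(frozenset(d["genes"]), frozenset(d["samples"])) for d in payload
    ]


def write_objective_trace(trace: Sequence[float], path: str | Path) -> None:
    pd.DataFrame(
        {"iteration": range(len(trace)), "objective": list(trace)}
    ).to_csv(path, sep="\t", index=False)
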