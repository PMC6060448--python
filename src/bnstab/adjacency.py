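"""Functional adjacency matrices of Boolean networks.

``A(F)`` is the n-by-n Boolean matrix with ``a_ij = 1`` iff flipping ``x_j``
changes ``f_i`` for at least one assignment of the remaining arguments
(functional, not syntactic, dependence).  Row ``i`` labels the influenced
node, column ``j`` the influencing node.  The influence graph has an edge
``x_j -> x_i`` when ``a_ij = 1``; the matrix is nilpotent under Boolean
powers iff that graph is acyclic, which certifies global convergence of the
network to a unique fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from . import expr as ex
from .network import BooleanNetwork, FixedAssignment, apply_fixings


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Bit matrix plus node labels; ``perm`` records the original indices
    (``perm[k]`` = position in the original ordering of the node now at k)."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    perm: tuple[int, ...] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, ij):
        return int(self.matrix[ij])

    def position(self, label: str) -> int:
        return self.labels.index(label)

    def to_tsv(self) -> str:
        rows = ["\t".join(("",) + self.labels)]
        for nm, row in zip(self.labels, self.matrix.astype(int)):
            rows.append("\t".join([nm] + [str(v) for v in row]))
        return "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "AdjacencyMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")[1:]
        rows, labels = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            labels.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
        if labels != header:
            raise ValueError("row and column labels differ")
        return cls(np.array(rows, dtype=bool), tuple(labels))


@dataclass(frozen=True)
class VectorStats:
    """Row/column norms and the triangularity partial sums d(.)."""

    row_norms: tuple[int, ...]     # |a_i^r|, incoming-edge counts
    col_norms: tuple[int, ...]     # |a_j^c|, outgoing-edge counts
    d_rows: tuple[int, ...]        # d(a_i^r) = sum_{j<=i} a_ij
    d_cols: tuple[int, ...]        # d(a_j^c) = sum_{i<=j} a_ij


def compute_adjacency(net: BooleanNetwork,
                      fixings: Iterable[FixedAssignment] = (),
                      bind: bool = False) -> AdjacencyMatrix:
    """Functional adjacency matrix of ``net`` with the given nodes fixed.

    A fixed node's transition function becomes the constant, so its row is
    zero; other rules keep their dependence on it unless ``bind=True``, which
    substitutes the fixed values into every rule (zeroing the fixed columns
    and pruning edges that a propagated constant makes vacuous).

    Cost per entry is at most ``2**(l-1)`` evaluations for in-degree ``l``.
    """
    work = apply_fixings(net, fixings, bind=bind) if fixings or bind else net
    n = net.n
    m = np.zeros((n, n), dtype=bool)
    for i, f in enumerate(work.functions):
        for var in ex.support(f):
            if ex.depends_on(f, var):
                m[i, net.index[var]] = True
    return AdjacencyMatrix(m, net.names)


def vector_stats(A: AdjacencyMatrix) -> VectorStats:
    m = A.matrix.astype(int)
    n = A.n
    return VectorStats(
        row_norms=tuple(int(v) for v in m.sum(axis=1)),
        col_norms=tuple(int(v) for v in m.sum(axis=0)),
        d_rows=tuple(int(m[i, : i + 1].sum()) for i in range(n)),
        d_cols=tuple(int(m[: j + 1, j].sum()) for j in range(n)),
    )


def _permute(A: AdjacencyMatrix, order: list[int]) -> AdjacencyMatrix:
    m = A.matrix[np.ix_(order, order)]
    labels = tuple(A.labels[k] for k in order)
    base = A.perm if A.perm is not None else tuple(range(A.n))
    return AdjacencyMatrix(m, labels, tuple(base[k] for k in order))


def permute_by_row_norm(A: AdjacencyMatrix) -> AdjacencyMatrix:
    """Symmetric reorder by ascending row norm; stable on ties."""
    norms = A.matrix.sum(axis=1)
    order = sorted(range(A.n), key=lambda i: (norms[i], i))
    return _permute(A, order)


def permute_by_col_norm(A: AdjacencyMatrix) -> AdjacencyMatrix:
    """Symmetric reorder by ascending column norm; stable on ties."""
    norms = A.matrix.sum(axis=0)
    order = sorted(range(A.n), key=lambda j: (norms[j], j))
    return _permute(A, order)


def boolean_power(A: AdjacencyMatrix, k: int) -> AdjacencyMatrix:
    """Boolean k-th power (OR/AND matrix product)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    m = A.matrix
    out = m
    for _ in range(k - 1):
        out = (out.astype(np.uint8) @ m.astype(np.uint8)) > 0
    return AdjacencyMatrix(out, A.labels, A.perm)


def nilpotency_index(A: AdjacencyMatrix) -> int | None:
    """Smallest k <= n with Boolean power zero, or None.

    A nilpotent Boolean matrix of size n vanishes by power n, so searching up
    to n is exact.
    """
    m = A.matrix
    out = m
    for k in range(1, A.n + 1):
        if not out.any():
            return k
        out = (out.astype(np.uint8) @ m.astype(np.uint8)) > 0
    return None


def is_strictly_triangular(A: AdjacencyMatrix, side: str = "lower") -> bool:
    """Strictly lower: zeros on and above the diagonal (dually for upper)."""
    if side == "lower":
        return not np.triu(A.matrix, k=0).any()
    if side == "upper":
        return not np.tril(A.matrix, k=0).any()
    raise ValueError("side must be 'lower' or 'upper'")


def is_acyclic(A: AdjacencyMatrix) -> bool:
    """No directed cycle in the influence graph (edge j->i when a_ij=1)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(A.n))
    rows, cols = np.nonzero(A.matrix)
    g.add_edges_from(zip(cols, rows))
    return nx.is_directed_acyclic_graph(g)


def iterate_adjacency(net: BooleanNetwork,
                      fixings: Iterable[FixedAssignment] = (),
                      k: int = 1, cap: int = 12) -> AdjacencyMatrix:
    """Adjacency of the k-fold composed map ``F^k`` (exact, exponential in n).

    Satisfies the elementwise bound ``A(F^k) <= (A(F))^(k)``.
    """
    n = net.n
    if n > cap:
        raise ValueError(f"n={n} exceeds the exhaustive cap ({cap})")
    if k < 1:
        raise ValueError("k must be a positive integer")
    stepf = net.compile_step(fixings)
    size = 1 << n
    image = [stepf(x) for x in range(size)]
    comp = list(image)
    for _ in range(k - 1):
        comp = [image[y] for y in comp]
    m = np.zeros((n, n), dtype=bool)
    for j in range(n):
        bit = 1 << j
        for x in range(size):
            if x & bit:
                continue
            diff = comp[x] ^ comp[x | bit]
            if diff:
                for i in range(n):
                    if (diff >> i) & 1:
                        m[i, j] = True
    return AdjacencyMatrix(m, net.names)
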