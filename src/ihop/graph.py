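"""Graph and dataset containers for transductive collective classification.

The substrate is an undirected, non-negatively weighted graph with a sparse
adjacency matrix ``A`` (zero diagonal) and a per-node degree table
``D_ii = sum_j A_ij``.  A collective-classification dataset adds a node
feature matrix ``X`` (n x f), a partial label matrix ``Y`` (n x l, rows
meaningful for the labeled set ``S``), and disjoint train/val/test node sets.

Self-contribution of a node to its own representation is always handled by
the node term of the propagation kernel, never by the neighborhood operator:
``A`` therefore carries a strictly zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "CCDataset",
    "NormalizedOperator",
    "make_operator",
    "get_subgraph",
]

OPERATOR_KINDS = ("row-mean", "gcn-renorm", "raw-adjacency")


@dataclass
class Graph:
    """Undirected weighted graph over contiguous 0-based node ids.

    Parameters
    ----------
    n : int
        Number of nodes.
    A : scipy.sparse.csr_matrix
        Symmetric ``n x n`` adjacency with non-negative weights and an
        all-zero diagonal.
    """

    n: int
    A: sp.csr_matrix

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A, dtype=np.float64)
        self.A.sort_indices()

    @property
    def degree(self) -> np.ndarray:
        """Weighted degree: row sums of the adjacency."""
        return np.asarray(self.A.sum(axis=1)).ravel()

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Undirected edge set as sorted ``(u, v)`` pairs, ``u < v``."""
        coo = self.A.tocoo()
        return {(int(min(i, j)), int(max(i, j))) for i, j in zip(coo.row, coo.col)}

    @property
    def n_edges(self) -> int:
        return self.A.nnz // 2

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges,
        weights=None,
    ) -> "Graph":
        """Build a graph from an iterable of (u, v) pairs.

        Duplicate and reversed pairs collapse to a single undirected edge;
        self-loops are dropped (the kernel's node term owns the self
        contribution).  Without explicit weights every edge has weight 1.
        """
        edges = list(edges)
        if weights is None:
            weights = [1.0] * len(edges)
        seen: dict[tuple[int, int], float] = {}
        for (u, v), w in zip(edges, weights):
            u, v = int(u), int(v)
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            seen[key] = float(w)  # last occurrence wins; duplicates collapse
        if seen:
            rows, cols, vals = [], [], []
            for (u, v), w in seen.items():
                rows += [u, v]
                cols += [v, u]
                vals += [w, w]
            A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        else:
            A = sp.csr_matrix((n, n))
        return cls(n=n, A=A)

    def validate(self) -> None:
        """Raise ``ValueError`` if a structural invariant is violated."""
        if self.A.shape != (self.n, self.n):
            raise ValueError(f"adjacency shape {self.A.shape} != ({self.n}, {self.n})")
        if self.A.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal entries (self-loops)")
        if (self.A.data < 0).any():
            raise ValueError("adjacency has negative weights")
        if (abs(self.A - self.A.T) > 1e-12).nnz:
            raise ValueError("adjacency is not symmetric")


@dataclass
class NormalizedOperator:
    """A realized neighborhood operator F(A).

    ``row-mean`` is the degree-normalized mean aggregator ``D^-1 A`` (rows of
    isolated nodes are all-zero); ``gcn-renorm`` is the renormalized
    symmetric operator ``(D+I)^-1/2 A (D+I)^-1/2``; ``raw-adjacency`` is
    ``A`` itself (neighbor-count aggregation).
    """

    kind: str
    matrix: sp.csr_matrix


def make_operator(graph: Graph, kind: str) -> NormalizedOperator:
    """Realize the neighborhood aggregation operator F(A) for ``graph``."""
    A = graph.A
    deg = graph.degree
    if kind == "row-mean":
        inv = np.zeros_like(deg)
        nz = deg > 0
        inv[nz] = 1.0 / deg[nz]
        M = sp.diags(inv) @ A
    elif kind == "gcn-renorm":
        s = 1.0 / np.sqrt(deg + 1.0)
        M = sp.diags(s) @ A @ sp.diags(s)
    elif kind == "raw-adjacency":
        M = A.copy()
    else:
        raise ValueError(
            f"unknown operator kind {kind!r}; expected one of {OPERATOR_KINDS}"
        )
    return NormalizedOperator(kind=kind, matrix=sp.csr_matrix(M))


def get_subgraph(graph: Graph, seeds, C: int):
    """Extract the C-hop closure of ``seeds`` and its induced adjacency.

    Returns ``(nodes, A_sub, seed_map)`` where ``nodes`` is the sorted array
    of all nodes at BFS distance <= C from any seed, ``A_sub`` is the
    adjacency restricted to those nodes, and ``seed_map`` maps each seed to
    its row index within the subgraph.
    """
    if C < 0:
        raise ValueError("hop count C must be >= 0")
    seeds = np.asarray(sorted({int(s) for s in np.atleast_1d(seeds)}), dtype=np.int64)
    if seeds.size == 0:
        raise ValueError("seed set must be non-empty")
    if seeds.min() < 0 or seeds.max() >= graph.n:
        raise ValueError("seed ids out of range")

    visited = np.zeros(graph.n, dtype=bool)
    visited[seeds] = True
    frontier = seeds
    indptr, indices = graph.A.indptr, graph.A.indices
    for _ in range(C):
        if frontier.size == 0:
            break
        neigh = np.unique(
            np.concatenate([indices[indptr[u]: indptr[u + 1]] for u in frontier])
        ) if frontier.size else np.empty(0, dtype=np.int64)
        frontier = neigh[~visited[neigh]]
        visited[frontier] = True
    nodes = np.flatnonzero(visited)
    A_sub = graph.A[nodes][:, nodes].tocsr()
    pos = {int(g): i for i, g in enumerate(nodes)}
    seed_map = {int(s): pos[int(s)] for s in seeds}
    return nodes, A_sub, seed_map


@dataclass
class CCDataset:
    """A partially labeled attributed graph for collective classification.

    ``Y`` is stored as a dense ``n x l`` matrix whose rows are meaningful for
    the labeled set ``S`` (and, when ground truth is available, for the test
    set used in evaluation); all other rows are zero.  ``S`` is the labeled
    set (training plus validation nodes), ``U = V - S`` the unlabeled set.
    """

    graph: Graph
    X: np.ndarray
    Y: np.ndarray
    S: np.ndarray
    U: np.ndarray
    val: np.ndarray
    test: np.ndarray
    task: str  # "multi-class" | "multi-label"
    id_map: dict | None = None
    name: str = "dataset"
    _extra: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]

    @property
    def train(self) -> np.ndarray:
        """Labeled nodes used for gradient updates: S minus validation."""
        return np.setdiff1d(self.S, self.val)

    def row_normalize_features(self) -> None:
        """Normalize each feature row to sum to one (zero rows untouched)."""
        sums = self.X.sum(axis=1, keepdims=True)
        nz = sums.ravel() != 0
        self.X = self.X.astype(np.float64, copy=True)
        self.X[nz] /= sums[nz]

    def validate(self) -> None:
        self.graph.validate()
        n = self.graph.n
        if self.X.shape[0] != n:
            raise ValueError("feature row count does not match node count")
        if self.Y.shape[0] != n:
            raise ValueError("label matrix row count does not match node count")
        S, U = set(self.S.tolist()), set(self.U.tolist())
        if S & U:
            raise ValueError("labeled set S and unlabeled set U overlap")
        if S | U != set(range(n)):
            raise ValueError("S union U must cover all nodes")
        if not set(self.val.tolist()) <= S:
            raise ValueError("validation nodes must be labeled (val subset of S)")
        if not set(self.test.tolist()) <= U:
            raise ValueError("test nodes must be unlabeled (test subset of U)")
        Ys = self.Y[self.S]
        if self.task == "multi-class":
            if not np.all(Ys.sum(axis=1) == 1) or not np.isin(Ys, (0, 1)).all():
                raise ValueError("multi-class label rows must be one-hot")
        elif self.task == "multi-label":
            if not np.isin(Ys, (0, 1)).all() or not np.all(Ys.sum(axis=1) >= 1):
                raise ValueError(
                    "multi-label rows must be 0/1 with at least one positive"
                )
        else:
            raise ValueError(f"unknown task {self.task!r}")
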