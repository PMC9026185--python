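"""Seed-deterministic synthetic attributed graphs.

Three generators cover the behaviors the estimators must exhibit:

* a chain (path) graph with one-hot node attributes, for tracing exactly how
  far information travels per propagation layer and per outer iteration;
* random p-regular graphs, for neighborhood-growth accounting (the C-hop
  closure of a seed has at most ``1 + p * sum_{i<C} (p-1)^i`` nodes);
* homophilous planted-partition (block-model) graphs with class-conditional
  noisy features, for end-to-end recovery tests.  ``p_in > p_out`` makes
  linked nodes share labels (homophily); ``feature_snr`` scales how much the
  features alone reveal the class, so the two information channels
  (structure vs features) can be turned on and off independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import comb

from .graph import CCDataset, Graph

__all__ = [
    "SyntheticSpec",
    "make_chain",
    "make_regular",
    "make_homophily",
    "edge_homophily",
    "expected_edge_homophily",
]


@dataclass
class SyntheticSpec:
    """Parameters of the block-model generator.

    ``feature_snr`` is the weight of a node's class-indicator columns
    relative to unit-scale non-negative noise in its feature row; 0 means
    pure noise.  ``label_rate`` is the fraction of nodes that are labeled
    (the standard semi-supervised protocol: 20% of nodes held out as test,
    10% of all nodes labeled, 20% of those labeled used for validation).
    """

    generator: str = "homophily-blocks"
    n: int = 1000
    p: int = 4  # degree, for the regular generator
    l: int = 4
    p_in: float = 0.04
    p_out: float = 0.004
    feature_snr: float = 1.0
    n_features: int | None = None
    multi_label: bool = False
    label_rate: float = 0.10
    test_frac: float = 0.20
    val_frac: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.label_rate < 1:
            raise ValueError("label_rate must lie in (0, 1)")
        if self.p_in < self.p_out:
            raise ValueError("homophilous regime requires p_in >= p_out")


def _splits(n: int, spec: SyntheticSpec, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_test = int(round(spec.test_frac * n))
    test = np.sort(perm[:n_test])
    pool = perm[n_test:]
    n_lab = max(2, int(round(spec.label_rate * n)))
    S = np.sort(pool[:n_lab])
    n_val = max(1, int(round(spec.val_frac * n_lab)))
    val = np.sort(rng.permutation(S)[:n_val])
    return S, val, test


def make_chain(n: int, n_classes: int = 2) -> CCDataset:
    """A path graph 0-1-...-(n-1) with one-hot attribute-identity features.

    Node i carries feature e_i, so every node's input is unique and
    perturbations can be traced hop by hop.  Labels alternate along the
    chain (node parity for two classes).  For n >= 5 the first four nodes
    form the labeled set (the last two of them validation) and the far end
    is the test node; shorter chains label the first two nodes only.
    """
    if n < 2:
        raise ValueError("chain needs at least 2 nodes")
    graph = Graph.from_edges(n, [(i, i + 1) for i in range(n - 1)])
    X = np.eye(n)
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), np.arange(n) % n_classes] = 1.0
    if n >= 5:
        S, val, test = np.array([0, 1, 2, 3]), np.array([2, 3]), np.array([n - 1])
    else:
        S, val, test = np.array([0, 1]), np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    U = np.setdiff1d(np.arange(n), S)
    ds = CCDataset(graph=graph, X=X, Y=Y, S=S, U=U, val=val, test=test,
                   task="multi-class", name=f"chain{n}")
    ds.validate()
    return ds


def make_regular(n: int, p: int, seed: int = 0) -> Graph:
    """A simple random p-regular graph on n nodes (n*p must be even)."""
    if (n * p) % 2 != 0:
        raise ValueError("n * p must be even for a p-regular graph")
    if p >= n:
        raise ValueError("degree p must be < n")
    g = nx.random_regular_graph(p, n, seed=seed)
    graph = Graph.from_edges(n, list(g.edges()))
    graph.validate()
    return graph


def _block_edges(z: np.ndarray, p_in: float, p_out: float,
                 rng: np.random.Generator):
    """Bernoulli edges over the upper triangle with block probabilities."""
    n = len(z)
    rows, cols = np.triu_indices(n, k=1)
    same = z[rows] == z[cols]
    probs = np.where(same, p_in, p_out)
    keep = rng.random(len(probs)) < probs
    return list(zip(rows[keep].tolist(), cols[keep].tolist()))


def make_homophily(spec: SyntheticSpec) -> CCDataset:
    """Planted-partition attributed graph with class-conditional features.

    Nodes are assigned to ``l`` (nearly) equal blocks; edges appear with
    probability ``p_in`` within a block and ``p_out`` across blocks.  A
    node's feature row is ``feature_snr`` on its class-indicator columns
    plus |N(0,1)| noise everywhere (rows are non-negative, so downstream
    row-normalization is well defined).  In multi-label mode each node
    additionally joins 0-2 secondary blocks; its label vector marks all
    memberships, and the indicator columns of every membership are boosted.
    """
    rng = np.random.default_rng(spec.seed)
    n, l = spec.n, spec.l
    if n < 5 * l:
        raise ValueError("need at least ~5 nodes per class")
    z = np.sort(np.arange(n) % l)  # near-equal block sizes, deterministic
    edges = _block_edges(z, spec.p_in, spec.p_out, rng)
    graph = Graph.from_edges(n, edges)

    f = spec.n_features or max(2 * l, 8)
    member = np.zeros((n, l))
    member[np.arange(n), z] = 1.0
    if spec.multi_label:
        extra_counts = rng.integers(0, 3, size=n)  # 0-2 extra memberships
        for i in range(n):
            others = np.delete(np.arange(l), z[i])
            take = rng.choice(others, size=extra_counts[i], replace=False)
            member[i, take] = 1.0
    X = np.abs(rng.normal(size=(n, f)))
    X[:, :l] += spec.feature_snr * member
    Y = member.copy()

    S, val, test = _splits(n, spec, rng)
    for c in range(l):
        if Y[S, c].sum() == 0:  # guarantee every label occurs in S
            donors = np.setdiff1d(np.flatnonzero(Y[:, c] == 1), test)
            S = np.sort(np.append(S, donors[0]))
    U = np.setdiff1d(np.arange(n), S)
    val = np.intersect1d(val, S)
    ds = CCDataset(
        graph=graph, X=X, Y=Y, S=S, U=U, val=val, test=test,
        task="multi-label" if spec.multi_label else "multi-class",
        name="homophily-blocks",
    )
    ds.validate()
    return ds


def edge_homophily(graph: Graph, z: np.ndarray) -> float:
    """Fraction of edges whose endpoints share a class."""
    coo = graph.A.tocoo()
    mask = coo.row < coo.col
    same = z[coo.row[mask]] == z[coo.col[mask]]
    return float(same.mean()) if same.size else float("nan")


def expected_edge_homophily(n: int, l: int, p_in: float, p_out: float) -> float:
    """Closed-form block-model expectation of :func:`edge_homophily`
    for l equal blocks of size n/l."""
    b = n / l
    within = l * comb(b, 2) * p_in
    between = (comb(n, 2) - l * comb(b, 2)) * p_out
    return float(within / (within + between))
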