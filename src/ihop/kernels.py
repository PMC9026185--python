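"""The generic graph propagation kernel and its named instantiations.

A single recursion generates the whole family::

    h_0 = X
    h_k = sigma_k( alpha * (Phi_k W_k^phi)  +  beta * F(A) (Psi_k W_k^psi) )

where ``Phi_k`` is the node term (the original features ``h_0``, the previous
layer ``h_{k-1}``, or absent), ``Psi_k`` the neighbor term (``h_{k-1}``,
predicted labels, or their concatenation), and ``F(A)`` a neighborhood
aggregation operator (degree-normalized mean, renormalized symmetric
Laplacian-style operator, raw adjacency, or entrywise max pooling).  The two
terms are combined by summation or concatenation; optional skip connections
add the previous layer back in.

Selecting these components reproduces feed-forward baselines, spectral and
mean/max-pooling graph convolutions, semi-supervised iterative classification,
and the node-information-preserving (NIP) kernels in one code path.

Node information morphing
-------------------------
In linear mode (identity weights and activations, node and neighbor terms
both reading ``h_{k-1}``) the recursion collapses to the binomial closed form
``h_k = (alpha*I + beta*F(A))^k h_0``, so the weight of a node's own 0-hop
features in its k-hop representation is ``alpha^k / (alpha+beta)^k`` -- it
decays exponentially with depth for any ``beta > 0``.  Skip connections slow
the decay to ``(alpha+1)^k / (alpha+beta+1)^k``; NIP kernels remove it
entirely by pinning the node term to ``h_0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import yaml

from .graph import Graph, NormalizedOperator, make_operator

__all__ = [
    "KernelSpec",
    "PRESETS",
    "make_kernel",
    "init_weights",
    "count_parameters",
    "forward_pass",
    "propagate",
    "h0_relative_importance",
    "linear_unroll",
]

#: alpha sentinel for per-node (D+I)^-1 scaling of the node term
ALPHA_INV_DEG_PLUS_1 = "inv-deg-plus-1"


@dataclass(frozen=True)
class KernelSpec:
    """One instantiation of the generic propagation kernel.

    Attributes
    ----------
    phi : {"h0", "h_prev", "none"}
        Node-term selector.
    psi : {"h_prev", "labels", "h_prev+labels", "none"}
        Neighbor-term selector; "labels" reads the current predicted-label
        matrix (iterative models).
    alpha : float or "inv-deg-plus-1"
        Node-term weight; the sentinel selects per-node (D+I)^-1 scaling.
    beta : float or None
        Neighbor-term weight (None when the neighbor term is absent).
    operator_kind : {"row-mean", "gcn-renorm", "raw-adjacency", "max-pool", None}
    combine : {"sum", "concat"}
        ``concat`` doubles the width handed to the next layer.
    tied_weights : bool
        Whether W_k^phi and W_k^psi are shared.
    skip : bool
        Additive previous-layer shortcut (projected through W_k^phi when the
        widths differ, i.e. at the input layer).
    C : int
        Number of propagation layers (differentiable hops).
    dims : int
        Hidden width d.
    activation : {"relu", "identity"}
    iterative : bool
        Whether the kernel participates in an outer label-refresh loop.
    """

    name: str
    phi: str = "h_prev"
    psi: str = "h_prev"
    alpha: float | str = 1.0
    beta: float | None = 1.0
    operator_kind: str | None = "row-mean"
    combine: str = "sum"
    tied_weights: bool = False
    skip: bool = False
    C: int = 2
    dims: int = 16
    activation: str = "relu"
    iterative: bool = False

    def __post_init__(self):
        if self.phi not in ("h0", "h_prev", "none"):
            raise ValueError(f"bad phi selector {self.phi!r}")
        if self.psi not in ("h_prev", "labels", "h_prev+labels", "none"):
            raise ValueError(f"bad psi selector {self.psi!r}")
        if self.combine not in ("sum", "concat"):
            raise ValueError(f"bad combine rule {self.combine!r}")
        if self.phi == "none" and self.psi == "none":
            raise ValueError("kernel needs at least one of node/neighbor terms")
        if self.tied_weights and self.phi != self.psi:
            raise ValueError("tied weights require identical phi/psi selectors")

    @property
    def uses_labels(self) -> bool:
        return "labels" in self.psi

    def replace(self, **kw) -> "KernelSpec":
        return dataclasses.replace(self, **kw)

    # -- plain-text (de)serialization so experiments are declarative --------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "KernelSpec":
        return cls.from_dict(yaml.safe_load(text))


#: Named instantiations of the generic kernel.  Models other than the
#: spectral GCN pair and the concatenating GS family carry skip connections.
PRESETS: dict[str, KernelSpec] = {
    # feature-only feed-forward baseline (node term only)
    "BL_NODE": KernelSpec(
        name="BL_NODE", phi="h0", psi="none", alpha=1.0, beta=None,
        operator_kind=None, skip=True,
    ),
    # structure-only baseline (neighbor term only, mean aggregation)
    "BL_NEIGH": KernelSpec(
        name="BL_NEIGH", phi="none", psi="h_prev", alpha=0.0, beta=1.0,
        operator_kind="row-mean", skip=True,
    ),
    # renormalized spectral convolution, tied weights, per-node (D+I)^-1 alpha
    "GCN": KernelSpec(
        name="GCN", phi="h_prev", psi="h_prev", alpha=ALPHA_INV_DEG_PLUS_1,
        beta=1.0, operator_kind="gcn-renorm", tied_weights=True, skip=False,
    ),
    # GCN with input- and output-layer shortcuts
    "GCN-S": KernelSpec(
        name="GCN-S", phi="h_prev", psi="h_prev", alpha=ALPHA_INV_DEG_PLUS_1,
        beta=1.0, operator_kind="gcn-renorm", tied_weights=True, skip=True,
    ),
    # mean-aggregation convolution, tied weights
    "GCN-MEAN": KernelSpec(
        name="GCN-MEAN", phi="h_prev", psi="h_prev", alpha=1.0, beta=1.0,
        operator_kind="row-mean", tied_weights=True, skip=True,
    ),
    # GraphSAGE-style mean aggregator: untied weights, concat combine
    "GS-MEAN": KernelSpec(
        name="GS-MEAN", phi="h_prev", psi="h_prev", alpha=1.0, beta=1.0,
        operator_kind="row-mean", combine="concat", skip=False,
    ),
    # GraphSAGE-style max-pool aggregator
    "GS-MAX": KernelSpec(
        name="GS-MAX", phi="h_prev", psi="h_prev", alpha=1.0, beta=1.0,
        operator_kind="max-pool", combine="concat", skip=False,
    ),
    # node-information-preserving mean kernel: node term pinned to h0
    "NIP-MEAN": KernelSpec(
        name="NIP-MEAN", phi="h0", psi="h_prev", alpha=1.0, beta=1.0,
        operator_kind="row-mean", skip=True,
    ),
    # semi-supervised iterative classification: one hop over neighbor labels
    "SS-ICA": KernelSpec(
        name="SS-ICA", phi="h0", psi="labels", alpha=1.0, beta=1.0,
        operator_kind="row-mean", skip=False, C=1, iterative=True,
    ),
    # iterative NIP kernel: neighbor term reads [h_{k-1}, Yhat]
    "I-HOP-MEAN": KernelSpec(
        name="I-HOP-MEAN", phi="h0", psi="h_prev+labels", alpha=1.0, beta=1.0,
        operator_kind="row-mean", skip=True, iterative=True,
    ),
}


def make_kernel(preset: str, **overrides) -> KernelSpec:
    """Return the named kernel spec, optionally overriding C/dims/etc."""
    if preset not in PRESETS:
        raise ValueError(
            f"unknown kernel preset {preset!r}; known: {sorted(PRESETS)}"
        )
    spec = PRESETS[preset]
    return spec.replace(**overrides) if overrides else spec


# ---------------------------------------------------------------------------
# layer widths and weight initialization
# ---------------------------------------------------------------------------

def layer_dims(spec: KernelSpec, f: int, l: int) -> list[dict]:
    """Per-layer input/output widths implied by the selectors.

    Returns one dict per layer with keys ``phi_in``, ``psi_in``, ``out``
    (any of the first two may be 0 when the term is absent).
    """
    dims = []
    w_prev = f
    for _ in range(1, spec.C + 1):
        phi_in = {"h0": f, "h_prev": w_prev, "none": 0}[spec.phi]
        psi_in = {
            "h_prev": w_prev,
            "labels": l,
            "h_prev+labels": w_prev + l,
            "none": 0,
        }[spec.psi]
        out = spec.dims * (2 if spec.combine == "concat" else 1)
        dims.append({"phi_in": phi_in, "psi_in": psi_in, "out": out})
        w_prev = out
    return dims


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_weights(
    spec: KernelSpec, f: int, l: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Glorot-initialized layer weights for a kernel of given widths."""
    params: dict[str, np.ndarray] = {}
    dims = layer_dims(spec, f, l)
    for k, d in enumerate(dims, start=1):
        if d["phi_in"]:
            params[f"W{k}_phi"] = _glorot(rng, d["phi_in"], spec.dims)
        if d["psi_in"] and not spec.tied_weights:
            params[f"W{k}_psi"] = _glorot(rng, d["psi_in"], spec.dims)
        # tied weights: the psi projection reuses W{k}_phi (single parameter)
    last = dims[-1]["out"] if dims else f
    params["W_L"] = _glorot(rng, last, l)
    params["b_L"] = np.zeros(l)
    return params


def count_parameters(spec: KernelSpec, f: int, l: int) -> int:
    """Number of trainable scalars (tied weights counted once)."""
    n = 0
    for k, d in enumerate(layer_dims(spec, f, l), start=1):
        if d["phi_in"]:
            n += d["phi_in"] * spec.dims
        if d["psi_in"] and not spec.tied_weights:
            n += d["psi_in"] * spec.dims
    last = layer_dims(spec, f, l)[-1]["out"] if spec.C else f
    n += last * l + l
    return n


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _resolve_alpha(spec: KernelSpec, A: sp.csr_matrix) -> np.ndarray | float:
    if spec.alpha == ALPHA_INV_DEG_PLUS_1:
        deg = np.asarray(A.sum(axis=1)).ravel()
        return 1.0 / (deg + 1.0)
    return float(spec.alpha)


def _act(name: str, Z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(Z, 0.0)
    if name == "identity":
        return Z
    raise ValueError(f"unknown activation {name!r}")


def _maxpool(A: sp.csr_matrix, Z: np.ndarray):
    """Entrywise max of each node's neighbors' rows of Z.

    Returns the pooled matrix and the argmax source index per entry
    (-1 where a node has no neighbors).  Permutation-invariant in the
    neighbor order by construction.
    """
    n, d = A.shape[0], Z.shape[1]
    out = np.zeros((n, d))
    argmax = np.full((n, d), -1, dtype=np.int64)
    indptr, indices = A.indptr, A.indices
    for i in range(n):
        nb = indices[indptr[i]: indptr[i + 1]]
        if nb.size == 0:
            continue
        block = Z[nb]
        j = np.argmax(block, axis=0)
        out[i] = block[j, np.arange(d)]
        argmax[i] = nb[j]
    return out, argmax


def forward_pass(
    spec: KernelSpec,
    params: dict[str, np.ndarray],
    X0: np.ndarray,
    A: sp.csr_matrix,
    labels_for_psi: np.ndarray | None = None,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    operator: NormalizedOperator | None = None,
):
    """Run the layered kernel; returns (h_C, cache-list for backprop).

    ``A`` is the (sub)graph adjacency; the aggregation operator is realized
    from it unless an explicit ``operator`` is supplied.  ``labels_for_psi``
    (n x l) is required iff the psi selector includes labels.  Dropout, when
    active, masks layer inputs and is rescaled (inverted dropout); pass
    ``dropout=0`` at inference.
    """
    if spec.uses_labels and labels_for_psi is None:
        raise ValueError("psi selector includes labels but none were given")
    M = None
    if spec.operator_kind not in (None, "max-pool"):
        if operator is not None:
            M = operator.matrix
        else:
            M = make_operator(Graph(n=A.shape[0], A=A), spec.operator_kind).matrix
    alpha = _resolve_alpha(spec, A)

    h_prev = np.asarray(X0, dtype=np.float64)
    h0 = h_prev
    caches = []
    for k in range(1, spec.C + 1):
        cache: dict = {"k": k}
        phi_in = {"h0": h0, "h_prev": h_prev, "none": None}[spec.phi]
        if spec.psi == "h_prev":
            psi_in = h_prev
        elif spec.psi == "labels":
            psi_in = labels_for_psi
        elif spec.psi == "h_prev+labels":
            psi_in = np.hstack([h_prev, labels_for_psi])
        else:
            psi_in = None

        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            keep = 1.0 - dropout
            if phi_in is not None:
                m = (rng.random(phi_in.shape) < keep) / keep
                cache["drop_phi"] = m
                phi_in = phi_in * m
            if psi_in is not None:
                m = (rng.random(psi_in.shape) < keep) / keep
                cache["drop_psi"] = m
                psi_in = psi_in * m

        node = neigh = None
        if phi_in is not None:
            W = params[f"W{k}_phi"]
            if phi_in.shape[1] != W.shape[0]:
                raise ValueError(
                    f"layer {k}: node-term width {phi_in.shape[1]} does not "
                    f"match weight shape {W.shape}"
                )
            proj = phi_in @ W
            node = proj * alpha[:, None] if isinstance(alpha, np.ndarray) else alpha * proj
            cache.update(phi_in=phi_in, node_proj=proj)
        if psi_in is not None:
            W = params.get(f"W{k}_psi", params.get(f"W{k}_phi"))
            if psi_in.shape[1] != W.shape[0]:
                raise ValueError(
                    f"layer {k}: neighbor-term width {psi_in.shape[1]} does "
                    f"not match weight shape {W.shape}"
                )
            Z = psi_in @ W
            if spec.operator_kind == "max-pool":
                pooled, argmax = _maxpool(A, Z)
                cache["argmax"] = argmax
            else:
                pooled = M @ Z
            neigh = spec.beta * pooled
            cache.update(psi_in=psi_in, Z=Z)

        if spec.combine == "concat":
            parts = [p for p in (node, neigh) if p is not None]
            pre = np.hstack(parts)
            cache["split"] = parts[0].shape[1] if len(parts) == 2 else None
        else:
            pre = (0 if node is None else node) + (0 if neigh is None else neigh)

        skip_mode = None
        if spec.skip:
            if h_prev.shape[1] == pre.shape[1]:
                pre = pre + h_prev
                skip_mode = "identity"
            elif phi_in is not None and spec.combine == "sum":
                # width mismatch (input layer): shortcut through the node
                # projection, the (alpha+1) form of the skip recursion
                pre = pre + cache["node_proj"]
                skip_mode = "projected"
        cache.update(pre=pre, h_prev=h_prev, skip_mode=skip_mode)
        h_prev = _act(spec.activation, pre)
        caches.append(cache)

    ctx = {"M": M, "alpha": alpha, "A": A, "h0": h0}
    return h_prev, (caches, ctx)


def propagate(
    spec: KernelSpec,
    weights: dict[str, np.ndarray],
    X0: np.ndarray,
    graph_or_A,
    labels_for_psi: np.ndarray | None = None,
) -> np.ndarray:
    """The layered kernel as a pure function: returns h_C (no output head).

    ``graph_or_A`` may be a :class:`~ihop.graph.Graph` or a sparse adjacency.
    With ``C=0`` the input features are returned unchanged.
    """
    A = graph_or_A.A if isinstance(graph_or_A, Graph) else sp.csr_matrix(graph_or_A)
    if spec.C == 0:
        return np.asarray(X0, dtype=np.float64)
    hC, _ = forward_pass(spec, weights, X0, A, labels_for_psi)
    return hC


# ---------------------------------------------------------------------------
# closed-form linear-mode analysis
# ---------------------------------------------------------------------------

def h0_relative_importance(
    alpha: float, beta: float, k: int, skip: bool = False
) -> float:
    """Relative weight of a node's own 0-hop features after k hops.

    ``alpha^k / (alpha+beta)^k`` in the plain linear recursion;
    ``(alpha+1)^k / (alpha+beta+1)^k`` with skip connections.  Equals 1 for
    ``beta = 0`` (no neighbor mixing) and decays strictly with k otherwise.
    """
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValueError("need alpha, beta >= 0 and alpha + beta > 0")
    if k < 0:
        raise ValueError("hop count k must be >= 0")
    if skip:
        return float((alpha + 1.0) ** k / (alpha + beta + 1.0) ** k)
    return float(alpha ** k / (alpha + beta) ** k)


def linear_unroll(
    alpha: float,
    beta: float,
    operator: NormalizedOperator | sp.spmatrix,
    k: int,
    X0: np.ndarray,
) -> np.ndarray:
    """Apply the binomial closed form (alpha*I + beta*F(A))^k to X0.

    Uses repeated sparse application (never dense matrix powering), so cost
    is O(k * nnz * f).
    """
    if k < 0:
        raise ValueError("hop count k must be >= 0")
    M = operator.matrix if isinstance(operator, NormalizedOperator) else sp.csr_matrix(operator)
    if M.shape[0] != M.shape[1] or M.shape[1] != X0.shape[0]:
        raise ValueError("operator must be square and conformable with X0")
    H = np.asarray(X0, dtype=np.float64)
    for _ in range(k):
        H = alpha * H + beta * (M @ H)
    return H
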