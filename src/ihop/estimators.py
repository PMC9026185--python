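"""Scikit-learn style estimators for collective node classification.

Three estimators cover the model families:

``PropagationKernelClassifier``
    Trains one differentiable propagation kernel (any non-iterative preset:
    feature/structure baselines, spectral or mean/max-pool convolutions, the
    node-information-preserving NIP-MEAN kernel) transductively on a
    :class:`~ihop.graph.CCDataset`.
``IHopClassifier``
    Wraps a kernel in the iterative higher-order loop: each outer iteration
    t trains a C-layer kernel whose neighbor term additionally reads the
    previous iteration's predicted labels (a non-differentiable constant),
    then refreshes predictions for every node.  After T iterations the
    receptive field spans K = T*C hops while the parameter count stays O(C).
``SSICAClassifier``
    The semi-supervised iterative classification special case: C = 1 and a
    neighbor term that reads predicted labels only.

Estimators follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``random_state`` determinism)
but ``fit`` accepts a ``CCDataset`` since transductive graph data does not
decompose into an (X, y) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._net import Adam, backward_pass, output_probs, wce_loss_and_grad
from .graph import CCDataset, get_subgraph
from .kernels import (
    KernelSpec,
    count_parameters,
    forward_pass,
    init_weights,
    make_kernel,
)
from .metrics import micro_f1

__all__ = [
    "TrainConfig",
    "IHopState",
    "EarlyStopper",
    "class_weights",
    "DivergenceError",
    "PropagationKernelClassifier",
    "IHopClassifier",
    "SSICAClassifier",
    "ihop_train",
    "ssica_train",
    "predict",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite; carries a state snapshot."""

    def __init__(self, message: str, snapshot=None):
        super().__init__(message)
        self.snapshot = snapshot


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the standard protocol:
    Adam at 1e-2, max 2000 epochs, min 50, patience 30 halved with the
    learning rate on exhaustion, stop after 2 consecutive exhaustions)."""

    lr: float = 1e-2
    batch_size: int = 128
    dims: int = 16
    l2: float = 0.0
    dropout: float = 0.0
    max_epochs: int = 2000
    min_epochs: int = 50
    patience: int = 30
    patience_loss_limit: int = 2
    use_wce: bool = True
    neighbor_samples: list[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must be <= max_epochs")
        for name in ("lr", "batch_size", "dims", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class IHopState:
    """State carried across outer iterations of an iterative model."""

    t: int
    T: int
    C: int
    Yhat: np.ndarray
    weights: dict = field(default_factory=dict)
    rng_seed: int = 0


def class_weights(Y_train: np.ndarray, l: int | None = None) -> np.ndarray:
    """Inverse-frequency label weights: w_i = (sum_j N_j) / (l * N_i).

    ``N_i`` is the number of training rows carrying label i.  The identity
    ``w_i * N_i = (sum_j N_j) / l`` holds for every label.  A label with no
    training samples is a configuration error (prune rare labels first).
    """
    Y = np.asarray(Y_train, dtype=np.float64)
    if l is None:
        l = Y.shape[1]
    N = Y.sum(axis=0)
    if np.any(N == 0):
        missing = np.flatnonzero(N == 0).tolist()
        raise ValueError(
            f"labels {missing} have no training samples; prune rare labels "
            "before training"
        )
    return N.sum() / (l * N)


class EarlyStopper:
    """Patience-with-annealing controller for validation loss.

    The no-improvement countdown starts only after ``min_epochs``.  When the
    countdown reaches the patience window, the learning rate and the
    patience are halved and the window restarts; after
    ``patience_loss_limit`` consecutive exhaustions (no improvement in
    between) training stops.  Any strict improvement resets both the window
    and the exhaustion count.
    """

    def __init__(self, lr: float, min_epochs: int = 50, patience: int = 30,
                 patience_loss_limit: int = 2):
        self.lr = lr
        self.min_epochs = min_epochs
        self.patience = patience
        self.limit = patience_loss_limit
        self.best = np.inf
        self.epoch = 0
        self.count = 0
        self.exhaustions = 0
        self.stop = False

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True on improvement."""
        self.epoch += 1
        improved = val_loss < self.best
        if improved:
            self.best = val_loss
            self.count = 0
            self.exhaustions = 0
        elif self.epoch > self.min_epochs:
            self.count += 1
            if self.count >= self.patience:
                self.exhaustions += 1
                if self.exhaustions >= self.limit:
                    self.stop = True
                else:
                    self.lr /= 2.0
                    self.patience = max(1, self.patience // 2)
                    self.count = 0
        return improved


def _batches(nodes: np.ndarray, size: int):
    for i in range(0, len(nodes), size):
        yield nodes[i: i + size]


def _sampled_subgraph(graph, seeds, C, q_per_hop, rng):
    """C-hop closure expanding at most q_k sampled neighbors per node/hop."""
    seeds = np.asarray(sorted({int(s) for s in seeds}), dtype=np.int64)
    indptr, indices = graph.A.indptr, graph.A.indices
    visited = set(seeds.tolist())
    frontier = list(seeds)
    kept_edges = []
    for hop in range(C):
        q = q_per_hop[min(hop, len(q_per_hop) - 1)]
        nxt = []
        for u in frontier:
            nb = indices[indptr[u]: indptr[u + 1]]
            if nb.size > q:
                nb = rng.choice(nb, size=q, replace=False)
            for v in nb:
                kept_edges.append((u, int(v)))
                if int(v) not in visited:
                    visited.add(int(v))
                    nxt.append(int(v))
        frontier = nxt
    nodes = np.asarray(sorted(visited), dtype=np.int64)
    pos = {g: i for i, g in enumerate(nodes)}
    from .graph import Graph
    A_sub = Graph.from_edges(
        len(nodes), [(pos[u], pos[v]) for u, v in kept_edges]
    ).A
    seed_map = {int(s): pos[int(s)] for s in seeds}
    return nodes, A_sub, seed_map


class PropagationKernelClassifier(BaseEstimator):
    """A single differentiable propagation kernel trained transductively.

    Parameters mirror :class:`TrainConfig`; ``kernel`` names a preset (or is
    a :class:`~ihop.kernels.KernelSpec`).  Mini-batches of labeled nodes are
    expanded to their C-hop closure, so a step touches at most that closure,
    never the full graph when it is smaller.

    Fitted attributes: ``spec_``, ``weights_``, ``omega_``, ``history_``
    (per-epoch validation loss), ``n_parameters_``, ``n_iter_``,
    ``materialized_counts_`` (subgraph sizes of first-epoch batches),
    ``classes_``.
    """

    def __init__(self, kernel="NIP-MEAN", C=2, dims=16, lr=1e-2,
                 batch_size=128, l2=0.0, dropout=0.0, max_epochs=2000,
                 min_epochs=50, patience=30, patience_loss_limit=2,
                 use_wce=True, neighbor_samples=None, row_normalize=True,
                 random_state=0):
        self.kernel = kernel
        self.C = C
        self.dims = dims
        self.lr = lr
        self.batch_size = batch_size
        self.l2 = l2
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.min_epochs = min_epochs
        self.patience = patience
        self.patience_loss_limit = patience_loss_limit
        self.use_wce = use_wce
        self.neighbor_samples = neighbor_samples
        self.row_normalize = row_normalize
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel.replace(C=self.C, dims=self.dims)
        return make_kernel(self.kernel, C=self.C, dims=self.dims)

    def _prepare(self, dataset: CCDataset) -> np.ndarray:
        dataset.validate()
        X = dataset.X.astype(np.float64, copy=True)
        if self.row_normalize:
            sums = X.sum(axis=1, keepdims=True)
            nz = sums.ravel() != 0
            X[nz] /= sums[nz]
        return X

    def _forward_nodes(self, dataset, X, params, spec, nodes, labels_full):
        """Kernel forward + output head for ``nodes`` via their C-hop closure."""
        nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        C_eff = spec.C if spec.operator_kind is not None else 0
        sub_nodes, A_sub, seed_map = get_subgraph(dataset.graph, nodes, C_eff)
        rows = np.asarray([seed_map[int(v)] for v in nodes])
        lab = labels_full[sub_nodes] if spec.uses_labels else None
        hC, _ = forward_pass(spec, params, X[sub_nodes], A_sub, lab)
        logits = hC @ params["W_L"] + params["b_L"]
        return logits[rows]

    def _train_kernel(self, dataset, X, spec, params, labels_full, rng,
                      lr0=None, record_materialized=False):
        """Inner mini-batch training of one kernel; early-stopped on val loss."""
        train, val = dataset.train, dataset.val
        l = dataset.n_labels
        omega = (class_weights(dataset.Y[train], l) if self.use_wce
                 else np.ones(l))
        self.omega_ = omega
        adam = Adam(params, lr=lr0 or self.lr, l2=self.l2)
        stopper = EarlyStopper(adam.lr, self.min_epochs, self.patience,
                               self.patience_loss_limit)
        best_params = {k: v.copy() for k, v in params.items()}
        history = []
        materialized = []
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(train)
            for batch in _batches(order, self.batch_size):
                if self.neighbor_samples:
                    sub_nodes, A_sub, seed_map = _sampled_subgraph(
                        dataset.graph, batch, spec.C, self.neighbor_samples, rng
                    )
                else:
                    C_eff = spec.C if spec.operator_kind is not None else 0
                    sub_nodes, A_sub, seed_map = get_subgraph(
                        dataset.graph, batch, C_eff
                    )
                if record_materialized and epoch == 1:
                    materialized.append(len(sub_nodes))
                rows = np.asarray([seed_map[int(v)] for v in batch])
                lab = labels_full[sub_nodes] if spec.uses_labels else None
                hC, cache = forward_pass(
                    spec, params, X[sub_nodes], A_sub, lab,
                    dropout=self.dropout, rng=rng,
                )
                logits = hC @ params["W_L"] + params["b_L"]
                loss, dRows = wce_loss_and_grad(
                    dataset.task, logits[rows], dataset.Y[batch], omega
                )
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite training loss at epoch {epoch}",
                        snapshot={"params": best_params, "epoch": epoch},
                    )
                dLogits = np.zeros_like(logits)
                dLogits[rows] = dRows
                grads = {"W_L": hC.T @ dLogits, "b_L": dLogits.sum(axis=0)}
                dH = dLogits @ params["W_L"].T
                grads.update(backward_pass(spec, params, cache, dH))
                adam.step(params, grads)
            if val.size:
                v_logits = self._forward_nodes(
                    dataset, X, params, spec, val, labels_full
                )
                vloss, _ = wce_loss_and_grad(
                    dataset.task, v_logits, dataset.Y[val], omega
                )
            else:
                vloss = loss
            history.append(vloss)
            if stopper.update(vloss):
                best_params = {k: v.copy() for k, v in params.items()}
            adam.lr = stopper.lr
            if stopper.stop:
                break
        params.update(best_params)
        if record_materialized:
            self.materialized_counts_ = materialized
        return history

    # ------------------------------------------------------------------
    def fit(self, dataset: CCDataset, y=None):
        spec = self._make_spec()
        if spec.iterative:
            raise ValueError(
                f"preset {spec.name!r} is iterative; use IHopClassifier/"
                "SSICAClassifier"
            )
        X = self._prepare(dataset)
        rng = np.random.default_rng(self.random_state)
        params = init_weights(spec, dataset.n_features, dataset.n_labels, rng)
        labels_full = np.zeros_like(dataset.Y)
        history = self._train_kernel(
            dataset, X, spec, params, labels_full, rng,
            record_materialized=True,
        )
        self.spec_ = spec
        self.weights_ = params
        self.history_ = history
        self.n_iter_ = len(history)
        self.n_parameters_ = count_parameters(
            spec, dataset.n_features, dataset.n_labels
        )
        self.classes_ = np.arange(dataset.n_labels)
        self._X_fit = X
        return self

    def _label_features(self, dataset):
        return np.zeros_like(dataset.Y)

    def predict_proba(self, dataset: CCDataset, nodes=None) -> np.ndarray:
        if nodes is None:
            nodes = np.arange(dataset.n)
        X = self._prepare(dataset)
        logits = self._forward_nodes(
            dataset, X, self.weights_, self.spec_, nodes,
            self._label_features(dataset),
        )
        return output_probs(dataset.task, logits)

    def predict(self, dataset: CCDataset, nodes=None) -> np.ndarray:
        """Hardened labels: argmax one-hot (multi-class) or 0.5 threshold."""
        P = self.predict_proba(dataset, nodes)
        if dataset.task == "multi-class":
            out = np.zeros_like(P)
            out[np.arange(len(P)), P.argmax(axis=1)] = 1.0
            return out
        return (P >= 0.5).astype(np.float64)

    def score(self, dataset: CCDataset, nodes=None) -> float:
        """Micro-F1 of hardened predictions against dataset ground truth."""
        if nodes is None:
            nodes = dataset.test
        nodes = np.asarray(nodes, dtype=np.int64)
        return micro_f1(self.predict(dataset, nodes), dataset.Y[nodes])


class IHopClassifier(PropagationKernelClassifier):
    """Iterative higher-order propagation around a differentiable kernel.

    Each outer iteration t = 1..T trains the C-layer kernel against the true
    labels of the training nodes, with the neighbor term reading the frozen
    predicted-label matrix of iteration t-1 (all zeros at t = 1), then
    refreshes predictions for every node.  Kernel weights are carried from
    one iteration to the next (set ``relearn_from_scratch`` to re-init), so
    the trainable parameter count is independent of T.

    Extra fitted attributes: ``Yhat_`` (final predicted labels, n x l),
    ``state_`` (:class:`IHopState`), ``trace_`` (validation micro-F1 per
    iteration).
    """

    def __init__(self, kernel="I-HOP-MEAN", C=2, dims=16, lr=1e-2,
                 batch_size=128, l2=0.0, dropout=0.0, max_epochs=2000,
                 min_epochs=50, patience=30, patience_loss_limit=2,
                 use_wce=True, neighbor_samples=None, row_normalize=True,
                 random_state=0, T=3, use_true_labels_for_S=True,
                 harden_labels=False, relearn_from_scratch=False):
        super().__init__(
            kernel=kernel, C=C, dims=dims, lr=lr, batch_size=batch_size,
            l2=l2, dropout=dropout, max_epochs=max_epochs,
            min_epochs=min_epochs, patience=patience,
            patience_loss_limit=patience_loss_limit, use_wce=use_wce,
            neighbor_samples=neighbor_samples, row_normalize=row_normalize,
            random_state=random_state,
        )
        self.T = T
        self.use_true_labels_for_S = use_true_labels_for_S
        self.harden_labels = harden_labels
        self.relearn_from_scratch = relearn_from_scratch

    def _neighbor_labels(self, dataset: CCDataset, Yhat: np.ndarray):
        """The label matrix the neighbor term reads: soft predictions, with
        training nodes' rows replaced by their known labels (never a node's
        own row -- the aggregation operator has zero diagonal)."""
        L = Yhat.copy()
        if self.harden_labels:
            if dataset.task == "multi-class":
                H = np.zeros_like(L)
                seen = L.any(axis=1)
                H[seen, L[seen].argmax(axis=1)] = 1.0
                L = H
            else:
                L = (L >= 0.5).astype(np.float64)
        if self.use_true_labels_for_S:
            train = dataset.train
            L[train] = dataset.Y[train]
        return L

    def fit(self, dataset: CCDataset, y=None):
        if self.T < 1:
            raise ValueError("iteration horizon T must be >= 1")
        spec = self._make_spec()
        X = self._prepare(dataset)
        rng = np.random.default_rng(self.random_state)
        params = init_weights(spec, dataset.n_features, dataset.n_labels, rng)
        Yhat = np.zeros_like(dataset.Y)
        trace = []
        history = []
        for t in range(1, self.T + 1):
            if self.relearn_from_scratch and t > 1:
                params = init_weights(
                    spec, dataset.n_features, dataset.n_labels, rng
                )
            lab = self._neighbor_labels(dataset, Yhat)
            history.append(
                self._train_kernel(
                    dataset, X, spec, params, lab, rng,
                    record_materialized=(t == 1),
                )
            )
            # refresh predictions for every node from the trained kernel
            logits = self._forward_nodes(
                dataset, X, params, spec, np.arange(dataset.n), lab
            )
            Yhat = output_probs(dataset.task, logits)
            val = dataset.val
            if val.size:
                trace.append(
                    micro_f1(self._harden(dataset.task, Yhat[val]),
                             dataset.Y[val])
                )
        self.spec_ = spec
        self.weights_ = params
        self.Yhat_ = Yhat
        self.trace_ = trace
        self.history_ = history
        self.n_iter_ = sum(len(h) for h in history)
        self.n_parameters_ = count_parameters(
            spec, dataset.n_features, dataset.n_labels
        )
        self.classes_ = np.arange(dataset.n_labels)
        self.state_ = IHopState(
            t=self.T, T=self.T, C=spec.C, Yhat=Yhat, weights=params,
            rng_seed=self.random_state,
        )
        return self

    @staticmethod
    def _harden(task, P):
        if task == "multi-class":
            out = np.zeros_like(P)
            out[np.arange(len(P)), P.argmax(axis=1)] = 1.0
            return out
        return (P >= 0.5).astype(np.float64)

    def _label_features(self, dataset):
        return self._neighbor_labels(dataset, self.Yhat_)

    def infer(self, dataset: CCDataset, T: int | None = None,
              Yhat0: np.ndarray | None = None) -> list[np.ndarray]:
        """Iterative inference with frozen weights.

        Starting from all-zero predicted labels (or ``Yhat0``), repeatedly
        predicts every node's labels with the fitted kernel, feeding each
        round's predictions to the next round's neighbor term.  Returns the
        predicted-label matrix after each of the T rounds; after round t a
        node's prediction depends on at most its t*C-hop neighborhood.
        """
        T = T or self.T
        X = self._prepare(dataset)
        Yhat = np.zeros_like(dataset.Y) if Yhat0 is None else Yhat0.copy()
        out = []
        for _ in range(T):
            lab = self._neighbor_labels(dataset, Yhat)
            logits = self._forward_nodes(
                dataset, X, self.weights_, self.spec_, np.arange(dataset.n),
                lab,
            )
            Yhat = output_probs(dataset.task, logits)
            out.append(Yhat)
        return out


class SSICAClassifier(IHopClassifier):
    """Semi-supervised ICA: a one-hop kernel over mean-aggregated neighbor
    labels plus the node's own features, re-learned every iteration."""

    def __init__(self, C=1, dims=16, lr=1e-2, batch_size=128, l2=0.0,
                 dropout=0.0, max_epochs=2000, min_epochs=50, patience=30,
                 patience_loss_limit=2, use_wce=True, neighbor_samples=None,
                 row_normalize=True, random_state=0, T=3,
                 use_true_labels_for_S=True, harden_labels=False,
                 relearn_from_scratch=False):
        super().__init__(
            kernel="SS-ICA", C=C, dims=dims, lr=lr, batch_size=batch_size,
            l2=l2, dropout=dropout, max_epochs=max_epochs,
            min_epochs=min_epochs, patience=patience,
            patience_loss_limit=patience_loss_limit, use_wce=use_wce,
            neighbor_samples=neighbor_samples, row_normalize=row_normalize,
            random_state=random_state, T=T,
            use_true_labels_for_S=use_true_labels_for_S,
            harden_labels=harden_labels,
            relearn_from_scratch=relearn_from_scratch,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _estimator_from_config(cls, config: TrainConfig, T: int, **kw):
    return cls(
        T=T, dims=config.dims, lr=config.lr, batch_size=config.batch_size,
        l2=config.l2, dropout=config.dropout, max_epochs=config.max_epochs,
        min_epochs=config.min_epochs, patience=config.patience,
        patience_loss_limit=config.patience_loss_limit,
        use_wce=config.use_wce, neighbor_samples=config.neighbor_samples,
        random_state=config.seed, **kw,
    )


def ihop_train(dataset: CCDataset, spec: KernelSpec | str,
               config: TrainConfig, T: int):
    """Train an iterative kernel; returns (IHopState, validation-F1 trace)."""
    kernel = spec if isinstance(spec, KernelSpec) else make_kernel(spec)
    clf = _estimator_from_config(IHopClassifier, config, T,
                                 kernel=kernel, C=kernel.C)
    clf.fit(dataset)
    return clf.state_, clf.trace_


def ssica_train(dataset: CCDataset, config: TrainConfig, T: int):
    """Train the semi-supervised ICA model; returns (state, trace)."""
    clf = _estimator_from_config(SSICAClassifier, config, T)
    clf.fit(dataset)
    return clf.state_, clf.trace_


def predict(state: IHopState, spec: KernelSpec, dataset: CCDataset,
            nodes, row_normalize: bool = True) -> np.ndarray:
    """Label probabilities for ``nodes`` given an iterative-model state.

    Extracts the C-hop closure of ``nodes``, runs the kernel with the
    state's weights and frozen predicted labels, and applies the task head
    (softmax / sigmoid).  Features are row-normalized by default, matching
    the estimators' training-time convention.
    """
    if state.Yhat.shape[1] != dataset.n_labels:
        raise ValueError("state label width does not match dataset")
    nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
    sub_nodes, A_sub, seed_map = get_subgraph(dataset.graph, nodes, spec.C)
    rows = np.asarray([seed_map[int(v)] for v in nodes])
    lab = state.Yhat[sub_nodes] if spec.uses_labels else None
    X = dataset.X[sub_nodes].astype(np.float64, copy=True)
    if row_normalize:
        sums = X.sum(axis=1, keepdims=True)
        nz = sums.ravel() != 0
        X[nz] /= sums[nz]
    hC, _ = forward_pass(spec, state.weights, X, A_sub, lab)
    logits = hC @ state.weights["W_L"] + state.weights["b_L"]
    return output_probs(dataset.task, logits[rows])
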