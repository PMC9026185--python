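"""Backpropagation, losses and the Adam optimizer for the kernel networks.

Everything here is deliberately explicit numpy: the forward recursion lives
in :mod:`ihop.kernels`; this module differentiates it layer by layer using
the caches the forward pass records.  Predicted-label inputs (the ``labels``
component of the neighbor term) are constants by construction -- no gradient
is ever formed with respect to them, which realizes the stop-gradient
between outer iterations of the iterative models.
"""

from __future__ import annotations

import numpy as np

from .kernels import KernelSpec

__all__ = [
    "backward_pass",
    "softmax",
    "sigmoid",
    "output_probs",
    "wce_loss_and_grad",
    "Adam",
]


def _acc(grads: dict, key: str, val: np.ndarray) -> None:
    if key in grads:
        grads[key] = grads[key] + val
    else:
        grads[key] = val


def backward_pass(
    spec: KernelSpec,
    params: dict[str, np.ndarray],
    cache_bundle,
    dH: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all layer weights.

    ``dH`` is the upstream gradient w.r.t. ``h_C``; ``cache_bundle`` is the
    second return of :func:`ihop.kernels.forward_pass`.  Tied weights
    accumulate both the node- and neighbor-projection gradients into the
    single shared matrix.
    """
    caches, ctx = cache_bundle
    M, alpha = ctx["M"], ctx["alpha"]
    grads: dict[str, np.ndarray] = {}
    for cache in reversed(caches):
        k = cache["k"]
        dPre = dH * (cache["pre"] > 0) if spec.activation == "relu" else dH
        dH_prev = np.zeros_like(cache["h_prev"])
        if cache["skip_mode"] == "identity":
            dH_prev += dPre

        dNode = dNeigh = None
        if spec.combine == "concat":
            split = cache["split"]
            if split is None:
                if "phi_in" in cache:
                    dNode = dPre
                else:
                    dNeigh = dPre
            else:
                dNode, dNeigh = dPre[:, :split], dPre[:, split:]
        else:
            if "phi_in" in cache:
                dNode = dPre
            if "psi_in" in cache:
                dNeigh = dPre

        if dNode is not None:
            dProj = (
                dNode * alpha[:, None] if isinstance(alpha, np.ndarray)
                else alpha * dNode
            )
            if cache["skip_mode"] == "projected":
                dProj = dProj + dPre  # the un-scaled shortcut branch
            phi_in = cache["phi_in"]
            _acc(grads, f"W{k}_phi", phi_in.T @ dProj)
            dPhi_in = dProj @ params[f"W{k}_phi"].T
            if "drop_phi" in cache:
                dPhi_in = dPhi_in * cache["drop_phi"]
            if spec.phi == "h_prev":
                dH_prev += dPhi_in
            # phi == "h0": gradient w.r.t. the raw inputs, not a parameter

        if dNeigh is not None:
            if spec.operator_kind == "max-pool":
                Z = cache["Z"]
                dZ = np.zeros_like(Z)
                argmax = cache["argmax"]
                valid = argmax >= 0
                np.add.at(dZ, (argmax[valid], np.nonzero(valid)[1]), dNeigh[valid])
            else:
                dZ = M.T @ dNeigh
            dZ = spec.beta * dZ
            psi_key = f"W{k}_psi" if f"W{k}_psi" in params else f"W{k}_phi"
            _acc(grads, psi_key, cache["psi_in"].T @ dZ)
            dPsi_in = dZ @ params[psi_key].T
            if "drop_psi" in cache:
                dPsi_in = dPsi_in * cache["drop_psi"]
            if spec.psi == "h_prev":
                dH_prev += dPsi_in
            elif spec.psi == "h_prev+labels":
                w_prev = cache["h_prev"].shape[1]
                dH_prev += dPsi_in[:, :w_prev]
            # label columns are detached: their gradient is dropped here

        dH = dH_prev
    return grads


# ---------------------------------------------------------------------------
# output head and losses
# ---------------------------------------------------------------------------

def softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def sigmoid(Z: np.ndarray) -> np.ndarray:
    out = np.empty_like(Z)
    pos = Z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-Z[pos]))
    e = np.exp(Z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def output_probs(task: str, logits: np.ndarray) -> np.ndarray:
    """Softmax rows (multi-class) or elementwise sigmoid (multi-label)."""
    if task == "multi-class":
        return softmax(logits)
    if task == "multi-label":
        return sigmoid(logits)
    raise ValueError(f"unknown task {task!r}")


def wce_loss_and_grad(
    task: str,
    logits: np.ndarray,
    Y: np.ndarray,
    omega: np.ndarray,
):
    """Class-imbalance-weighted cross-entropy; returns (loss, dLogits).

    ``omega`` holds one weight per label, inversely proportional to the
    label's training frequency.  Multi-class: the true class' log-probability
    is weighted.  Multi-label: the positive term of each label's binary
    cross-entropy is weighted.  Loss is the mean over rows; ``dLogits``
    carries the 1/B factor.
    """
    B = logits.shape[0]
    eps = 1e-12
    if task == "multi-class":
        P = softmax(logits)
        w_row = (Y * omega[None, :]).sum(axis=1)
        loss = -np.mean(w_row * np.log((P * Y).sum(axis=1) + eps))
        dLogits = w_row[:, None] * (P - Y) / B
    else:
        Ps = sigmoid(logits)
        pos = omega[None, :] * Y * np.log(Ps + eps)
        neg = (1.0 - Y) * np.log(1.0 - Ps + eps)
        loss = -np.mean((pos + neg).sum(axis=1))
        dLogits = (omega[None, :] * Y * (Ps - 1.0) + (1.0 - Y) * Ps) / B
    return float(loss), dLogits


class Adam:
    """Adam with optional decoupled-from-nothing classic L2 penalty."""

    def __init__(self, params: dict, lr: float = 1e-2, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.l2 = l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            if self.l2 > 0.0 and not key.startswith("b"):
                g = g + self.l2 * params[key]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            params[key] = params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
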