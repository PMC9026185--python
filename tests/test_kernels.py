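"""Kernel presets, the layered forward pass, and linear-mode closed forms."""

import numpy as np
import pytest

from ihop import (
    Graph,
    KernelSpec,
    h0_relative_importance,
    init_weights,
    linear_unroll,
    make_kernel,
    make_operator,
    propagate,
)
from ihop.kernels import layer_dims

from conftest import random_er_graph


def identity_weights(spec, f, C):
    W = {}
    for k in range(1, C + 1):
        W[f"W{k}_phi"] = np.eye(f)
        if not spec.tied_weights and spec.psi != "none":
            W[f"W{k}_psi"] = np.eye(f)
    W["W_L"] = np.eye(f)
    W["b_L"] = np.zeros(f)
    return W


# instantiation grid: (preset, phi, psi, operator, tied, combine, iterative)
GRID = [
    ("BL_NODE", "h0", "none", None, False, "sum", False),
    ("BL_NEIGH", "none", "h_prev", "row-mean", False, "sum", False),
    ("GCN", "h_prev", "h_prev", "gcn-renorm", True, "sum", False),
    ("GCN-S", "h_prev", "h_prev", "gcn-renorm", True, "sum", False),
    ("GCN-MEAN", "h_prev", "h_prev", "row-mean", True, "sum", False),
    ("GS-MEAN", "h_prev", "h_prev", "row-mean", False, "concat", False),
    ("GS-MAX", "h_prev", "h_prev", "max-pool", False, "concat", False),
    ("NIP-MEAN", "h0", "h_prev", "row-mean", False, "sum", False),
    ("SS-ICA", "h0", "labels", "row-mean", False, "sum", True),
    ("I-HOP-MEAN", "h0", "h_prev+labels", "row-mean", False, "sum", True),
]


class TestPresets:
    @pytest.mark.parametrize(
        "name,phi,psi,op,tied,combine,iterative", GRID,
        ids=[row[0] for row in GRID])
    def test_instantiation_grid(self, name, phi, psi, op, tied, combine,
                                iterative):
        spec = make_kernel(name)
        assert (spec.phi, spec.psi, spec.operator_kind) == (phi, psi, op)
        assert spec.tied_weights == tied
        assert spec.combine == combine
        assert spec.iterative == iterative

    def test_gcn_uses_per_node_alpha_and_skips_differ(self):
        assert make_kernel("GCN").alpha == "inv-deg-plus-1"
        assert not make_kernel("GCN").skip and make_kernel("GCN-S").skip

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown kernel preset"):
            make_kernel("GAT")

    def test_spec_yaml_roundtrip(self):
        spec = make_kernel("NIP-MEAN", C=3, dims=32)
        assert KernelSpec.from_yaml(spec.to_yaml()) == spec

    def test_tied_weights_require_matching_selectors(self):
        with pytest.raises(ValueError, match="tied"):
            KernelSpec(name="bad", phi="h0", psi="h_prev", tied_weights=True)


class TestForward:
    def test_zero_layers_returns_input(self, rng):
        g = Graph.from_edges(3, [(0, 1), (1, 2)])
        X = rng.normal(size=(3, 4))
        spec = make_kernel("NIP-MEAN", C=0, dims=4)
        assert np.array_equal(propagate(spec, {}, X, g), X)

    def test_isolated_node_neighbor_term_vanishes(self, rng):
        """With no neighbors the NIP update reduces to the node projection."""
        g = Graph.from_edges(1, [])
        X = rng.normal(size=(1, 4))
        spec = make_kernel("NIP-MEAN", C=3, dims=4,
                           activation="identity").replace(skip=False)
        W = identity_weights(spec, 4, 3)
        W["W3_phi"] = rng.normal(size=(4, 4))
        h = propagate(spec, W, X, g)
        assert np.allclose(h, X @ W["W3_phi"])

    def test_concat_combine_doubles_width(self, rng):
        g = random_er_graph(8, 0.4, rng)
        X = rng.normal(size=(8, 5))
        spec = make_kernel("GS-MEAN", C=2, dims=6)
        dims = layer_dims(spec, 5, 3)
        assert dims[0]["out"] == 12 and dims[1]["phi_in"] == 12
        params = init_weights(spec, 5, 3, rng)
        h = propagate(spec, params, X, g)
        assert h.shape == (8, 12)

    def test_width_mismatch_names_layer(self, rng):
        g = random_er_graph(6, 0.5, rng)
        spec = make_kernel("NIP-MEAN", C=2, dims=4)
        params = init_weights(spec, 5, 2, rng)
        with pytest.raises(ValueError, match="layer 1"):
            propagate(spec, params, rng.normal(size=(6, 7)), g)

    def test_maxpool_invariant_to_neighbor_order(self, rng):
        """Max pooling must not depend on adjacency storage order."""
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)]
        X = rng.normal(size=(4, 5))
        spec = make_kernel("GS-MAX", C=2, dims=6)
        params = init_weights(spec, 5, 3, rng)
        out = [
            propagate(spec, params, X, Graph.from_edges(4, order))
            for order in (edges, edges[::-1], [edges[i] for i in (2, 0, 4, 1, 3)])
        ]
        assert np.array_equal(out[0], out[1])
        assert np.array_equal(out[0], out[2])

    def test_labels_required_when_psi_reads_them(self, rng):
        g = random_er_graph(5, 0.5, rng)
        spec = make_kernel("SS-ICA", dims=4)
        params = init_weights(spec, 3, 2, rng)
        with pytest.raises(ValueError, match="labels"):
            propagate(spec, params, rng.normal(size=(5, 3)), g)

    def test_presets_differ_exactly_through_their_selectors(self, rng):
        """NIP-MEAN vs GCN-MEAN on a fixed fixture: outputs differ, and
        forcing the node term back to h_prev recovers the mean-kernel pass."""
        g = random_er_graph(5, 0.6, rng)
        X = rng.normal(size=(5, 4))
        nip = make_kernel("NIP-MEAN", C=2, dims=4, activation="identity")
        gcn_mean = make_kernel("GCN-MEAN", C=2, dims=4, activation="identity")
        W = identity_weights(nip, 4, 2)
        h_nip = propagate(nip, W, X, g)
        h_mean = propagate(gcn_mean, identity_weights(gcn_mean, 4, 2), X, g)
        assert not np.allclose(h_nip, h_mean)
        nip_as_wl = nip.replace(phi="h_prev")
        assert np.allclose(propagate(nip_as_wl, W, X, g), h_mean)


class TestLinearMode:
    @pytest.mark.parametrize("skip", [False, True])
    def test_layered_kernel_equals_binomial_closed_form(self, skip, rng):
        """Identity weights/activations collapse the recursion to
        (alpha I + beta F(A))^k h0, with alpha -> alpha+1 under skips."""
        for _ in range(5):
            n = int(rng.integers(5, 50))
            g = random_er_graph(n, 0.15, rng)
            X = rng.normal(size=(n, n))
            for k in range(5):
                spec = make_kernel("GCN-MEAN", C=k, dims=n,
                                   activation="identity").replace(skip=skip)
                W = identity_weights(spec, n, k)
                h = propagate(spec, W, X, g)
                M = make_operator(g, "row-mean")
                alpha = 2.0 if skip else 1.0
                ref = linear_unroll(alpha, 1.0, M, k, X)
                assert np.abs(h - ref).max() < 1e-10
                # independent dense matrix-power oracle
                dense = np.linalg.matrix_power(
                    alpha * np.eye(n) + M.matrix.toarray(), k) @ X
                assert np.abs(h - dense).max() < 1e-10

    def test_unroll_degenerate_cases(self, rng):
        g = random_er_graph(6, 0.5, rng)
        M = make_operator(g, "row-mean")
        X = rng.normal(size=(6, 3))
        assert np.array_equal(linear_unroll(1.0, 1.0, M, 0, X), X)
        assert np.allclose(linear_unroll(1.0, 0.0, M, 1, X), X)
        with pytest.raises(ValueError):
            linear_unroll(1.0, 1.0, M, -1, X)


class TestH0Importance:
    def test_reference_values(self):
        # the 2^-k decay of equally weighted node/neighbor mixing
        assert h0_relative_importance(1, 1, 3) == pytest.approx(0.125)
        assert h0_relative_importance(1, 0, 7) == 1.0
        assert h0_relative_importance(1, 1, 1, skip=True) == pytest.approx(2 / 3)

    def test_strictly_decreasing_and_skip_dominates(self):
        """Node information decays with depth; skips slow the decay."""
        for alpha in (0.5, 1.0, 2.0):
            for beta in (0.5, 1.0, 3.0):
                prev = prev_s = np.inf
                for k in range(1, 8):
                    v = h0_relative_importance(alpha, beta, k)
                    vs = h0_relative_importance(alpha, beta, k, skip=True)
                    assert v < prev and vs < prev_s
                    assert vs >= v
                    prev, prev_s = v, vs

    def test_rejects_degenerate_weights(self):
        with pytest.raises(ValueError):
            h0_relative_importance(0, 0, 1)
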