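"""Training engine: class weights, early stopping, iterative inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihop import (
    EarlyStopper,
    IHopClassifier,
    PropagationKernelClassifier,
    SSICAClassifier,
    SyntheticSpec,
    TrainConfig,
    class_weights,
    make_chain,
    make_homophily,
    make_kernel,
    make_operator,
)
from ihop.estimators import ihop_train, predict
from ihop.synthetic import make_regular


@pytest.fixture(scope="module")
def small_ds():
    return make_homophily(SyntheticSpec(
        n=200, l=3, p_in=0.10, p_out=0.01, feature_snr=0.5, seed=7))


FAST = dict(max_epochs=60, min_epochs=10, patience=8, dims=8)


class TestClassWeights:
    def test_balanced_labels_get_unit_weight(self):
        Y = np.repeat(np.eye(2), 10, axis=0)
        assert np.allclose(class_weights(Y), [1.0, 1.0])

    def test_imbalanced_labels(self):
        Y = np.repeat(np.eye(2), [30, 10], axis=0)
        assert np.allclose(class_weights(Y), [2 / 3, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=2,
                    max_size=12))
    def test_weight_times_count_is_constant(self, counts):
        """w_i * N_i = (sum_j N_j) / l for every label."""
        Y = np.repeat(np.eye(len(counts)), counts, axis=0)
        w = class_weights(Y)
        expected = sum(counts) / len(counts)
        assert np.allclose(w * np.asarray(counts), expected)

    def test_unseen_label_is_configuration_error(self):
        Y = np.zeros((4, 3))
        Y[:, 0] = 1
        with pytest.raises(ValueError, match="prune"):
            class_weights(Y)


class TestEarlyStopper:
    def test_strictly_decreasing_loss_never_stops(self):
        s = EarlyStopper(lr=1e-2, min_epochs=50, patience=30)
        for epoch in range(2000):
            s.update(1.0 / (epoch + 1))
            assert not s.stop
        assert s.lr == 1e-2  # never annealed

    def test_constant_loss_stops_after_two_exhaustions(self):
        """min 50 epochs + 30 patience -> first exhaustion at 80, the
        halved window (15) runs out at 95."""
        s = EarlyStopper(lr=1e-2, min_epochs=50, patience=30)
        epoch = 0
        while not s.stop:
            epoch += 1
            s.update(1.0)
        assert epoch == 95
        assert s.lr == pytest.approx(5e-3)  # halved exactly once

    def test_improvement_at_patience_boundary_resets_window(self):
        s = EarlyStopper(lr=1e-2, min_epochs=0, patience=5)
        for _ in range(4):
            s.update(1.0)
        s.update(0.5)  # improvement on the final countdown epoch
        assert s.count == 0 and s.exhaustions == 0 and not s.stop


class TestTrainConfig:
    def test_rejects_inconsistent_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(min_epochs=100, max_epochs=50)


class TestClassifier:
    def test_multiclass_probabilities_sum_to_one(self, small_ds):
        clf = PropagationKernelClassifier(
            kernel="NIP-MEAN", random_state=0, **FAST).fit(small_ds)
        P = clf.predict_proba(small_ds, small_ds.test)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert P.shape == (len(small_ds.test), small_ds.n_labels)

    def test_same_seed_reproduces_bit_identical_predictions(self, small_ds):
        runs = [
            PropagationKernelClassifier(
                kernel="GCN-MEAN", random_state=3, **FAST
            ).fit(small_ds).predict_proba(small_ds)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0], runs[1])

    def test_sklearn_param_interface(self):
        from sklearn.base import clone
        clf = IHopClassifier(T=4, C=3)
        params = clf.get_params()
        assert params["T"] == 4 and params["C"] == 3
        clone(clf)  # must be cloneable from constructor params

    def test_iterative_preset_rejected_by_plain_classifier(self, small_ds):
        with pytest.raises(ValueError, match="iterative"):
            PropagationKernelClassifier(kernel="I-HOP-MEAN").fit(small_ds)


class TestIHop:
    def test_parameter_count_independent_of_horizon(self, small_ds):
        """O(C) parameters: the horizon T never adds weights."""
        sizes = []
        for T in (1, 3):
            clf = IHopClassifier(T=T, random_state=0, **FAST).fit(small_ds)
            sizes.append((clf.n_parameters_,
                          sum(v.size for v in clf.weights_.values())))
        assert sizes[0] == sizes[1]
        assert sizes[0][0] == sizes[0][1]

    def test_first_iteration_sees_no_predicted_labels(self, small_ds):
        """With all-zero Yhat the label columns contribute nothing: the
        augmented kernel equals the plain NIP pass with the label rows of
        the neighbor weights removed."""
        clf = IHopClassifier(T=1, random_state=1, use_true_labels_for_S=False,
                             **FAST).fit(small_ds)
        state = clf.state_
        state.Yhat = np.zeros_like(state.Yhat)
        spec = clf.spec_
        probs = predict(state, spec, small_ds, small_ds.test)

        nip = make_kernel("NIP-MEAN", C=spec.C, dims=spec.dims)
        l = small_ds.n_labels
        trimmed = dict(state.weights)
        for k in range(1, spec.C + 1):
            trimmed[f"W{k}_psi"] = state.weights[f"W{k}_psi"][:-l]
        helper = PropagationKernelClassifier(kernel="NIP-MEAN",
                                             C=spec.C, dims=spec.dims)
        helper.spec_, helper.weights_ = nip, trimmed
        probs_nip = helper.predict_proba(small_ds, small_ds.test)
        assert np.allclose(probs, probs_nip, atol=1e-12)

    def test_training_does_not_mutate_frozen_labels(self, small_ds):
        clf = IHopClassifier(T=2, random_state=0, **FAST)
        clf.fit(small_ds)
        # refit against an explicitly frozen label matrix: bit-identical
        clf2 = IHopClassifier(T=2, random_state=0, **FAST).fit(small_ds)
        for key in clf.weights_:
            assert np.array_equal(clf.weights_[key], clf2.weights_[key])

    def test_batch_step_touches_only_the_hop_closure(self):
        """A training step materializes exactly the C-hop BFS closure of its
        batch: at most 1 + p * sum_{i<C}(p-1)^i nodes on a p-regular graph,
        and never the whole graph when b*p^C < n."""
        p, C, n = 3, 2, 400
        graph = make_regular(n, p, seed=1)
        ds = make_homophily(SyntheticSpec(n=n, l=2, p_in=0.02, p_out=0.005,
                                          feature_snr=1.0, seed=0))
        ds.graph = graph  # keep features/labels, swap in the regular graph
        clf = PropagationKernelClassifier(
            kernel="NIP-MEAN", C=C, batch_size=1, random_state=0,
            max_epochs=1, min_epochs=1, patience=1, dims=4)
        clf.fit(ds)
        bound = 1 + p * sum((p - 1) ** i for i in range(C))
        assert clf.materialized_counts_
        assert max(clf.materialized_counts_) <= bound < n

    def test_trace_and_wrapper_api(self, small_ds):
        state, trace = ihop_train(small_ds, "I-HOP-MEAN",
                                  TrainConfig(max_epochs=40, min_epochs=10,
                                              patience=6, dims=8, seed=0),
                                  T=2)
        assert state.T == 2 and len(trace) == 2
        assert state.Yhat.shape == (small_ds.n, small_ds.n_labels)
        assert np.allclose(state.Yhat.sum(axis=1), 1.0, atol=1e-9)


class TestSSICA:
    def test_mean_aggregated_neighbor_labels(self):
        """A node whose two neighbors carry labels (1,0) and (0,1) sees the
        averaged neighbor-label feature (0.5, 0.5)."""
        ds = make_chain(3)
        L = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        M = make_operator(ds.graph, "row-mean").matrix
        assert np.allclose((M @ L)[1], [0.5, 0.5])

    def test_first_iteration_is_feature_only(self, small_ds):
        """With Yhat = 0 (and no training-label substitution) the neighbor
        term of SS-ICA vanishes: predictions match a label-blind kernel."""
        clf = SSICAClassifier(T=1, random_state=5, use_true_labels_for_S=False,
                              **FAST).fit(small_ds)
        state = clf.state_
        state.Yhat = np.zeros_like(state.Yhat)
        probs = predict(state, clf.spec_, small_ds, small_ds.test)

        blind = clf.spec_.replace(psi="none", beta=None, operator_kind=None)
        helper = PropagationKernelClassifier()
        helper.spec_, helper.weights_ = blind, state.weights
        probs_blind = helper.predict_proba(small_ds, small_ds.test)
        assert np.allclose(probs, probs_blind, atol=1e-12)
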