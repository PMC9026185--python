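# ihop — propagation kernels and iterative higher-order inference for collective node classification

`ihop` implements a family of graph propagation kernels and an iterative
learning/inference loop for **collective classification**: predicting the
labels of unlabeled nodes in a partially labeled, attributed network by
exploiting both node features and neighborhood structure.  Typical use
cases are protein-function prediction on protein–protein interaction
networks, topic classification on citation graphs, and interest prediction
in social networks — any transductive setting where linked nodes carry
correlated labels (homophily).

## The model

Everything is an instantiation of one layered recursion.  With feature
matrix `X` (n×f), adjacency `A` (symmetric, zero diagonal), and degree
matrix `D`:

```
h_0 = X
h_k = σ_k( α · Φ_k W_kφ  +  β · F(A) Ψ_k W_kψ ),   k = 1..C
```

- `Φ_k` is the **node term** (`h_0`, `h_{k-1}`, or absent),
- `Ψ_k` the **neighbor term** (`h_{k-1}`, predicted labels `Ŷ`, or both),
- `F(A)` the aggregation operator: mean `D⁻¹A`, renormalized symmetric
  `(D+I)^{-1/2} A (D+I)^{-1/2}`, raw counts `A`, or entrywise max-pooling,
- node and neighbor parts combine by sum or concatenation, optionally with
  skip connections.

Choosing these components reproduces a feed-forward baseline (`BL_NODE`),
a structure-only baseline (`BL_NEIGH`), spectral and mean/max-pool graph
convolutions (`GCN`, `GCN-S`, `GCN-MEAN`, `GS-MEAN`, `GS-MAX`), iterative
classification (`SS-ICA`), and the **node-information-preserving** kernels
(`NIP-MEAN`, `I-HOP-MEAN`).

Two ideas carry the package:

1. **Node information morphing.**  In linear mode the common WL-style
   choice `Φ_k = Ψ_k = h_{k-1}` collapses to
   `h_k = (αI + βF(A))^k h_0`, so the weight of a node's own features in
   its k-hop representation is `α^k/(α+β)^k` — it decays exponentially
   with depth (`2^{-k}` for equal weighting).  Skip connections slow the
   decay to `(α+1)^k/(α+β+1)^k`; NIP kernels eliminate it by pinning the
   node term to `h_0`.
2. **Iterative higher-order propagation (I-HOP).**  Instead of stacking K
   differentiable layers (memory `O(p^K)` on degree-p graphs), a C-layer
   kernel is trained T times; each iteration's neighbor term additionally
   reads the *previous* iteration's predicted labels as a detached
   constant.  After T iterations the receptive field spans `K = T·C` hops
   while parameters stay `O(C)` and each mini-batch only materializes the
   C-hop closure of its seed nodes.

Training uses mini-batch Adam (lr 1e-2), Glorot initialization, row-
normalized features, class-imbalance-weighted cross-entropy
`ω_i = (Σ_j N_j)/(l·N_i)`, and patience-with-annealing early stopping
(min 50 epochs, patience 30, both learning rate and patience halved on
exhaustion, stop after two consecutive exhaustions).

## Worked example

```python
from ihop import (SyntheticSpec, make_homophily,
                  PropagationKernelClassifier, IHopClassifier)

# homophilous planted-partition graph, weak features:
# structure is informative, features are nearly noise
ds = make_homophily(SyntheticSpec(n=1000, l=4, p_in=0.04, p_out=0.004,
                                  feature_snr=0.3, seed=11))
feats = PropagationKernelClassifier(kernel="BL_NODE", max_epochs=300,
                                    random_state=11).fit(ds)
nip = PropagationKernelClassifier(kernel="NIP-MEAN", max_epochs=300,
                                  random_state=11).fit(ds)
ihop = IHopClassifier(T=3, max_epochs=300, random_state=11).fit(ds)

print(f"feature-only baseline  test micro-F1: {feats.score(ds):.3f}")
print(f"NIP-MEAN (C=2)         test micro-F1: {nip.score(ds):.3f}")
print(f"I-HOP (C=2, T=3)       test micro-F1: {ihop.score(ds):.3f}")
```

prints

```
feature-only baseline  test micro-F1: 0.325
NIP-MEAN (C=2)         test micro-F1: 0.690
I-HOP (C=2, T=3)       test micro-F1: 0.995
```

The feature-only baseline is near chance (4 classes, feature SNR 0.3); a
2-hop NIP kernel recovers most of the block structure from the graph; the
iterative model, which also feeds mean-aggregated neighbor labels back in,
recovers it almost perfectly.  `ihop.trace_` holds the per-iteration
validation micro-F1 (`[0.95, 1.0, 1.0]` here) and `ihop.n_parameters_`
(836) does not change with `T`.

The estimators follow scikit-learn conventions (`get_params`,
`set_params`, `clone`, fitted attributes with trailing underscores); `fit`
takes a `CCDataset` (graph + features + partial labels + splits), built by
the generators in `ihop.synthetic` or loaded from plain-text files with
`ihop.load_dataset`.

## Command line

```sh
ihop simulate --n 500 --l 4 --seed 1 --out data/          # write a dataset
ihop train --config config.yaml --kernel I-HOP-MEAN --t 3 --out run/
ihop infer --run-dir run/ --config config.yaml --t 5 --out pred/
ihop evaluate results_grid.csv                            # shortfall/rank/wins
```

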