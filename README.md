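# enzgraph

Graph deep learning on protein structures for **enzyme function
prediction** and **catalytic-site annotation**.

Enzymes are classified by four-level Enzyme Commission (EC) numbers
(class.subclass.sub-subclass.sub-sub-subclass), and their chemistry is
carried out by a handful of catalytic residues that are often close in
the folded structure but far apart in sequence. `enzgraph` turns each
protein chain into a residue graph — one-hot amino-acid identities *X*
plus per-residue sequence embeddings *E* as node features, and a binary
contact map *A* (Cα–Cα distance < 9 Å, with Cβ/centroid fallback for
residues missing the alpha carbon) as edges — and trains a graph
convolutional network to predict all EC classes of the chain as
independent sigmoid outputs. Gradient saliency over the trained network
then scores every residue for its contribution to a predicted class;
the top 10% of residues are reported as putative catalytic sites and
benchmarked against annotated sites with window matching and a
resampling null.

## Model

The network stacks local-extremum graph convolutions (LEConv),

```
h_i' = ReLU( h_i W1 + Σ_{j∈N(i)} e_{ji} (h_i W2 − h_j W3) )
```

and cluster graph convolutions (ClusterGCNConv),

```
H' = ReLU( (Ã + λ·diag(Ã)) H W1 + H W2 ),   Ã = (D + I)⁻¹ (A + I)
```

followed by global mean pooling, two ReLU fully-connected layers, and a
per-class sigmoid output so one chain can carry several EC numbers.
Training minimizes the focal loss
`FL(p_t) = −(1 − p_t)^γ log(p_t)` (γ = 2), which down-weights
well-classified examples and counteracts the severe negative-class
imbalance of deep EC levels, using Adam with early stopping.

Per-residue importance for a class *c* is the L1 norm of
`∂p_c / ∂[X|E]` per node (Saliency; InputXGradient is also available),
min–max normalized to [0, 1].

## Worked example

Real protein language models (ProtT5-class) are injected through the
`PrecomputedEmbedder`; the example below uses the bundled deterministic
reference embedder and fully synthetic structures with planted catalytic
motifs, so it runs anywhere in about a minute.

```python
from enzgraph import (GraphEnzymeClassifier, ReferenceEmbedder,
                      EmbedderSpec, stratified_kfold, node_saliency,
                      top_fraction_residues, default_dataset_spec,
                      generate_dataset)
from enzgraph.pipeline import dataset_from_tables, graphs_from_dataset

synthetic = generate_dataset(default_dataset_spec(
    n_classes=3, n_chains_per_class=40, seed=0))
labeled = dataset_from_tables(synthetic.chains, synthetic.intervals)
graphs = graphs_from_dataset(labeled,
                             ReferenceEmbedder(EmbedderSpec(dim=16, seed=0)))

folds = stratified_kfold(labeled, k=5, seed=0)
test = [graphs[i] for i in folds[0]]
train = [g for i, g in enumerate(graphs) if i not in set(folds[0])]

clf = GraphEnzymeClassifier(layer_dims=(32, 32, 32), fc_dims=(32, 16),
                            lr=1e-3, max_epochs=400, seed=0)
clf.fit(train)
print("held-out micro-F1:", round(clf.score(test), 3))

smap = node_saliency(test[0], clf.params_, clf.config_, target_class=3)
print("top-10% residues:", top_fraction_residues(smap, 0.10))
print("planted sites:   ", sorted(synthetic.catalytic[test[0].chain_ref].positions))
```

Output (seed 0):

```
held-out micro-F1: 0.952
top-10% residues: [3, 6, 12, 13, 16, 61, 62, 64, 88, 92]
planted sites:    [2, 13, 92]
```

The classifier recovers the synthetic EC labels of unseen chains
(micro-F1 0.952 over 24 held-out chains × 12 hierarchy classes). Of the
first test chain's three planted catalytic residues, two (13 and 92)
fall exactly inside the top-10% saliency set and the third (2) is missed
by a single position — a random draw of 10 residues from a 100-residue
chain would hit 0.3 of the 3 sites in expectation.

The same pipeline is scriptable from the shell:

```bash
enzgraph simulate --classes 3 --n 40 --seed 0 --out data/
enzgraph build-dataset --structures data/structures --intervals data/intervals.tsv --out built/
enzgraph train --data built/ --out model.npz --seed 0
enzgraph predict --model model.npz --data built/ --out preds.tsv
enzgraph explain --model model.npz --data built/ --out saliency.tsv
enzgraph evaluate --model model.npz --data built/ \
    --structures data/structures --catalytic data/catalytic.tsv --out eval/
```

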