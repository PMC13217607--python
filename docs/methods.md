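# Methods

## Problem and data model

A protein chain of length *L* is represented as an undirected graph.
Nodes are residues; each carries a one-hot identity over the 20 standard
amino acids (nonstandard residues, including selenocysteine and
pyrrolysine, map to 'X' and encode as an all-zero row) and a *d*-dim
sequence embedding. One representative coordinate is kept per residue:
the alpha carbon when present, else the beta carbon, else the centroid
of the residue's heavy (non-hydrogen) atoms — the fallback keeps
low-resolution structures with missing backbone atoms usable. Edges
connect residue pairs whose representative coordinates lie **strictly
within 9 Å** (a widely used contact cutoff that keeps consecutive
backbone residues, spaced ~3.8 Å, always connected while limiting
long-range noise); the adjacency is binary, symmetric, with a zero
diagonal. Self-loops are not stored — the cluster convolution adds the
identity internally through Ã = (D + I)⁻¹(A + I).

Structure files are parsed with gemmi (PDB required, mmCIF accepted).
Only the first model of multi-model files is used; residues are ordered
by author numbering plus insertion code and renumbered 1..L; among
alternate locations the first encountered is kept. Waters and
non-amino-acid hetero groups are dropped.

## Labels

EC numbers are hierarchical, 1–4 components. Chains acquire labels by
mapping their accession span onto annotation intervals; a mapping is
excluded when its length overlap is below 100 residues **and** its
fraction overlap is below 0.90 (so short chains must be nearly fully
covered), and EC numbers annotated only to the 2nd digit are dropped.
The fraction-overlap denominator is the chain span length, so a short
chain fully inside an interval scores 1.0. The label space contains
every observed EC at all its hierarchy levels (ancestor-closed), pruned
of classes with fewer than `min_positives` (default 5) positive chains;
target vectors are ancestor-closed binary vectors, one sigmoid output
per class. Two splitters are provided: a temporal holdout (train on an
old annotation snapshot; test only on ECs that appear exclusively in the
newer snapshot, with previously known ECs removed from test labels to
avoid leakage) and an iterative-stratification k-fold. The
stratification is the greedy rarest-label-first scheme augmented with a
repair pass (single-item moves that reduce residual imbalance) and up to
8 seeded restarts; for every class with at least k positives the
per-fold positive count deviates from total/k by at most 1, and the
result is deterministic per seed.

## Network and training

Input H⁰ = [X | E]. Defaults: two LEConv layers, one ClusterGCNConv
layer (widths 256/256/256), λ = 1, two fully-connected ReLU layers
(128/64), then one sigmoid per class. The layer equations are given in
the README. Since layer widths, λ, and the learning rate are free
architectural choices, all are configuration-driven.

Focal loss with γ = 2 (configurable), reduced by arithmetic mean over
classes and batch; probabilities are clamped to [1e−7, 1 − 1e−7] to keep
the logarithm finite. Optimization is Adam (default lr 1e−4), batch size
20 implemented as per-graph forward passes with gradient accumulation
(variable-size graphs make tensor batching pointless on CPU). Training
runs at most 500 epochs and stops early when **none** of training loss,
validation loss, or validation micro-F1 (threshold 0.5) improves for 30
consecutive epochs; the checkpoint with the best validation micro-F1 is
returned. All weights are Glorot-uniform; the LEConv aggregation
weights W2/W3 are additionally scaled by 1/√(expected_degree) (default
expected degree 10, roughly the 9 Å contact-map degree) because the
neighbor sum otherwise inflates activation variance at initialization,
saturating the sigmoids and stalling training. Everything is seeded:
initialization, epoch shuffling, splits.

The network and its gradients run on a small reverse-mode autodiff
engine over numpy (`enzgraph._autodiff`) — the package has no
deep-learning-framework dependency. Analytic gradients are validated
against central finite differences in the test suite (relative error
< 1e−4), and both graph layers plus the composed forward pass are
checked against independent brute-force dense implementations
(max |Δ| ≤ 1e−6 over 100 random graphs).

## Embeddings

The embedding interface requires only an L×d matrix of finite values
per sequence. `PrecomputedEmbedder` serves matrices computed offline by
a real protein language model (ProtT5-class models emit d = 1024).
`ReferenceEmbedder` is the bundled deterministic stand-in used by tests
and synthetic experiments: each residue's row is a seeded random
projection of the one-hot content of its ±2-residue window plus a
hash-derived phase of the exact window string, so rows are
context-sensitive, reproducible bit-for-bit, and identical whenever two
windows are identical. It is intentionally only weakly informative so
that synthetic training must also exploit structure.

## Attribution and catalytic-site evaluation

For a chosen class, the gradient of the output **probability** (not the
pre-sigmoid logit; after min–max normalization the two differ only in
degenerate cases) with respect to every entry of H⁰ is computed by
backpropagation. Per residue, the absolute entries are summed across
feature dimensions (L1 aggregation; Saliency) or first multiplied by
the input (InputXGradient), then min–max normalized to [0, 1]
per chain; an all-constant raw map normalizes to all zeros. The top
ceil(0.10·L) residues (ties broken toward lower positions) are the
predicted catalytic sites.

Evaluation gates each chain on a correct prediction: the target class
must be truly positive and predicted above the decision threshold
(default 0.5). For gated chains the package reports (i) coverage — the
number of annotated residues with a predicted residue within a ±w
sequence window (w = 0..5) or within r Å (r = 3..7) of Euclidean
distance; (ii) precision — the fraction of predicted residues in-window
of an annotated one; (iii) the mean Euclidean distance from each
predicted residue to its nearest annotated site, compared against a
null in which the same number of positions is drawn uniformly **without
replacement** across the chain, 1,000 replicates by default; the
z-score uses the sample (ddof = 1) SD of the replicates, and a
degenerate null (zero SD) yields NaN with a warning.

## Synthetic data

The generator emulates the pipeline's three inputs — CA-only PDB
structures, accession-interval EC tables, and catalytic-site tables —
with planted ground truth. Backbones are compact self-avoiding random
walks: consecutive spacing exactly 3.8 Å, non-consecutive pairs ≥ 3 Å
apart, confined to a sphere of radius 4·L^(1/3) Å (compact-globule
scaling). Each synthetic class is a motif of three residue identities
(e.g. S/H/D, a catalytic-triad-like pattern) planted at sequence
positions pairwise ≥ 10 apart but steered during the walk to lie
pairwise within 6 Å — catalytic residues close in the fold, distant in
sequence, which forces the structure graph rather than local sequence
windows to carry the signal. Background residues are sampled uniformly
from the letters unused by any motif, making the planted identities the
class-defining feature. The geometry is deliberately minimal: no
secondary structure, no side chains, no Ramachandran statistics — so
passing tests demonstrate that the architecture can learn and localize
spatially clustered sequence-structure signals, not that it reaches any
particular accuracy on real proteomes.

## Reference experiment (what `scripts/acceptance.py` computes)

Problem sizes, chosen once: 3 classes × 40 chains of 80–120 residues,
reference embeddings d = 16, layers 32/32/32 with FC 32/16, lr 1e−3,
batch 20, ≤ 400 epochs, patience 30, 9 Å cutoff — small enough to train
in under a minute on one CPU while leaving a stable signal. One of five
stratified folds (20%) is held out entirely; the estimator's internal
validation split comes out of the remaining 80%. Reported quantities:
micro-averaged precision/recall/F1/accuracy/MCC on the held-out fold at
threshold 0.5; the percentage of planted catalytic residues on
correctly-predicted held-out chains hit exactly by top-10% saliency;
the ratio of that count to the uniform-random expectation
(hypergeometric mean, ceil(0.1·L)·|sites|/L per chain); and the mean
nearest-distance z-scores against the 1,000-replicate null (mean z and
the fraction of chains with z < 0). All randomness derives from the
single `--seed` argument.

## Known limitations

- Synthetic geometry is not physically realistic protein structure;
  results on it bound what the architecture can do, not field accuracy.
- The reference embedder is not a protein language model; with real
  pLM embeddings the absolute numbers would differ.
- Training is CPU-bound pure numpy: fine at these problem sizes,
  unsuitable for corpus-scale training (tens of thousands of chains).
- Redundancy reduction (e.g. 95%-identity clustering) is delegated: the
  dataset builder accepts a precomputed representative list but does not
  cluster sequences itself.
- The z-score null assumes exchangeable positions along the chain; it
  corrects for chain length but not for composition or geometry biases
  of real catalytic pockets.
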