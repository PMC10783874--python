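# Methods

This note records the modelling choices behind the package: the procedure
and its assumptions, the defaults that matter, what the synthetic data does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Graphs and features

Molecules are heavy-atom 2-D topology graphs: implicit hydrogens, no 3-D
information, no tautomer or salt normalisation. Atom order is the parser's
emission order and is frozen before masking — it is the index that the
sinusoidal positional encodings address, so featurization is bit-
deterministic per SMILES. Directed edges are enumerated as (bond order) ×
(forward, reverse), which fixes the dual graph's node order too.

All features are ordered categorical one-hot blocks, because they double
as reconstruction targets: each block is a separate softmax target, which
keeps the "multi-label" reconstruction objective well defined with no
continuous targets. Every open-ended block carries a final "other" slot so
out-of-vocabulary values (elements beyond the common organic set, degrees
above 5, exotic hybridizations) degrade gracefully rather than erroring.

* Atom blocks (47 columns): element (12 common organics + other), degree
  0–5+other, formal charge −2…+2+other, chirality tag, implicit-H count
  0–4+other, hybridization, aromaticity, ring membership.
* Bond blocks (15 columns): type (single/double/triple/aromatic/other),
  conjugation, ring membership, stereo.

The dual-graph node for directed bond (u, v) carries the features of its
starting atom u concatenated with the bond's features. Concatenation
rather than addition: the two feature spaces have different dimensions, so
a sum is not defined. The predecessors of dual node (v, w) are the dual
nodes (u, v) with u ∈ N(v)\{w}; the exclusion keeps messages from
reflecting straight back along the reverse edge.

## Masking

Each branch masks independently at ratio ρ (default 0.6). The masked count
is ⌊ρ·n⌋, clamped so that whenever ρ > 0 and n ≥ 2 at least one element is
masked and at least one stays visible — a deterministic rule with no
rounding ambiguity. The two directions of one bond are distinct maskable
elements (directed masking); one seed per molecule is split into node and
dual sub-streams, so the branch masks are mutually independent but jointly
reproducible. Note that within a branch, sampling a *fixed count* without
replacement makes element pairs very slightly negatively correlated
(O(1/n)); pairwise independence of reverse directions holds exactly only
across branches and asymptotically within one.

Masked elements are removed, not zeroed: the encoder's visible inputs
contain only visible features, visible positions, and visible-visible
adjacency, so encoder blindness to masked content holds by construction.
The node and edge masks are not correlated (masking an atom does not mask
its incident bonds); nothing in the training objective requires coupling,
and independent masks maximise task diversity.

## Architecture

Both branches share one architecture. A GNN-Attention block computes
queries, keys and values each with a small K-hop message-passing GNN and
then applies multi-head scaled dot-product attention over all elements of
the molecule; locality enters only through the GNN stage, attention is
full. Within a block's GNN stack the hop weights are shared across the K
hops (a recurrent-style stack); together with the feed-forward width 256
this puts the reference configuration (hidden 100, 6 encoder / 2 decoder
blocks per branch, 3 hops, 2 heads) at 2,615,470 trainable scalars ≈ 2.6 M
— the parameter budget is treated as an architecture constraint.

Numerical arrangement: σ = ReLU throughout; feed-forward is two linear
layers with ReLU; normalisation is post-norm (LayerNorm after residual
addition). Positional rows are added after the input linear projection,
and re-added to every position at feature reordering. The mask token is
one learned vector per branch (not per position), initialised from
N(0, 0.02²). Queries, keys and values use unshared GNN weights. The
encoder ends with neighbor-sum aggregation, a long-range residual from the
projected raw features, and feed-forward + LayerNorm; the decoder is M < N
blocks of the same form over the full adjacency, followed by a linear
reconstruction head per branch. The node head's width is the atom feature
dimensionality; the edge head reconstructs the bond blocks (the head-atom
half of a dual node's input is the node branch's job). The graph-level
READOUT (mean pooling) is used only downstream, not during pre-training.

Batches are disjoint unions: molecules are concatenated into one graph and
attention is restricted to same-molecule pairs by an additive block-
diagonal mask (-1e9 off-block). This is semantically identical to padding
with attention masks and avoids materialising padded slots.

All computation is float64 NumPy on a small reverse-mode autodiff engine
(`batmannet.autodiff`), whose gradients are pinned by central-difference
checks; this makes every run bit-reproducible given its seed.

## Pre-training

Per step: sample a batch, draw fresh masks per molecule from
per-(seed, step, molecule) substreams, encode, reorder, decode, compute
the loss, and take an Adam step (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at the
Noam rate `d^-0.5 · min(step^-0.5, step·warmup^-1.5)` with global-norm
gradient clipping at 5. Branch losses are *averaged* over masked elements
(not summed) so L_node and L_edge are scale-comparable across molecules
and batch sizes; the normalisation is recorded in checkpoint metadata.
The corpus is filtered to ≥ 2 heavy atoms, split 9:1 train/validation by
seed, and the best-validation checkpoint is retained. Validation loss uses
masking but no updates. Defaults: batch 32, ρ = 0.6, warmup 1000 steps
(100 for the short desk-scale smoke configurations, which run ≤ 500
steps); molecules with no bonds contribute no edge-branch loss; a step in
which neither branch has a masked element is an error.

## Downstream

Fine-tuning runs a full-graph encoder pass (ρ = 0), mean READOUT per
branch, and a two-layer MLP head per branch; the final prediction is the
arithmetic mean of the two heads, taken on logits before the sigmoid for
classification (averaging in logit space keeps the combination linear in
the heads). A molecule with no bonds falls back to the node head alone.
All encoder weights are updated by default; a freeze-encoder flag gives
the linear-probe regime. Missing labels are excluded from the loss and the
per-task metrics; test metrics are reported as mean ± sd over seeds after
validation-based model selection.

Scaffold splitting groups molecules by Bemis–Murcko scaffold, sorts groups
by size (largest first, then key, for determinism) and fills train, then
valid, then test to the 8:1:1 targets. An acyclic molecule's Murcko
scaffold is empty; each such molecule counts as its own scaffold group
(keyed by canonical SMILES) rather than pooling all chain molecules into
one giant pseudo-scaffold.

The pair (drug–drug interaction style) head takes both molecules'
node ⊕ edge readouts, applies one MLP to both orderings of the
concatenation and averages the logits, so the score is symmetric by
construction; it is trained on frozen encoder embeddings.

The validity probe follows the standard linear-probing protocol:
standardised features and an almost unregularised logistic regression
(C = 100), averaged over stratified splits — the probe measures linearly
decodable information in the embedding, not its scale (with default L2
strength, the post-LayerNorm scale of trained embeddings would confound
the comparison against an untrained control).

## Synthetic data

The fixture generator enumerates simple organic chemotypes — linear and
branched alkanes C2–C10, alcohols, amines, ethers, halides, nitriles,
acids, benzene and pyridine derivatives with mono- and di-substitution —
canonicalised and deduplicated, shuffled per seed (capacity ≈ 330
molecules). Validity is guaranteed by construction. These corpora emulate
small drug-like 2-D topologies; they do not contain fused ring systems,
macrocycles, charged/zwitterionic species, stereocenters or the scale of a
real pre-training corpus, so passing tests demonstrate that the machinery
learns and transfers on separable desk-scale tasks, not benchmark-level
chemistry performance.

"Invalid" molecules for the representation probe are made by shuffling
atom-feature rows against a fixed topology (a non-identity permutation,
resampled until the degree block contradicts the adjacency; for fully
symmetric molecules whose feature rows are all identical, one atom's
degree block is cyclically shifted instead). Such graphs have no SMILES
serialisation — the invalid class is defined by feature–topology
inconsistency. A rule-based checker separates the classes perfectly; the
embedding probe is only asked to beat chance and an untrained control.

## Problem sizes and defaults used in the shipped checks

The test suite and examples use a desk-scale configuration (hidden 32,
2 encoder / 1 decoder blocks, 2 hops, 2 heads, feed-forward 64) with
corpora of 32–256 generated molecules, 300–800 pre-training steps for
transfer checks and ≤ 500 steps for the reconstruction-accuracy check —
sizes chosen so a complete run finishes in minutes on one CPU core while
still exercising every stage end to end. The reference configuration is
instantiated (for parameter accounting) but not pre-trained here.

## Known limitations

* No 3-D geometry, stereochemistry-aware conformers, or tautomer handling.
* Single-process CPU training only; no mixed precision or distribution.
* The exact feature vocabulary is a design choice in the lineage of
  directed-message-passing encoders; other vocabularies would change the
  reconstruction-target dimensionality (and the parameter count slightly).
* Whether Q/K/V GNNs should share weights, and whether branch outputs
  should be averaged as probabilities rather than logits, are genuinely
  open choices; the ones taken here are recorded above.
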