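# Methods

## Model

Molecules are undirected graphs over heavy atoms.  Atoms carry two
categorical features (atom-type index derived from the atomic number, 120
slots plus a reserved `[MASK]` slot; chirality tag with 3 slots) and bonds
two (bond type among single/double/triple/aromatic plus a self-loop slot;
bond direction with 3 slots).  Hydrogens are implicit.  Bonds are stored
once and expanded to both directions inside message passing.

The encoder is a GIN variant in the convention common to molecular
pretraining work: layer input `h_v` is updated by summing over neighbors
the neighbor embedding plus embedded edge features, adding a self-loop
message with its dedicated bond-type slot, and passing the aggregate
through a two-layer perceptron (D → 2D → D, ReLU inside) followed by
normalization; ReLU joins layers except after the last.  The molecule
embedding is the mean of final-layer node embeddings (sum available via
`readout="sum"`).  Defaults: 5 layers, D = 300, dropout 0 when
pretraining and 0.5 downstream.

### Normalization

Each GIN layer ends in batch normalization with running statistics
(momentum 0.1): batch statistics in training, stored running statistics at
evaluation.  This choice is load-bearing.  A per-node LayerNorm variant
(`norm="layer"`, retained as an option) produces directionally collapsed
molecule embeddings at initialization — all pairwise cosine similarities
above 0.96 — which starves the InfoNCE objective of logit spread and makes
training oscillate into the collapse saddle where every similarity is
equal and the loss pins at ln |B| with vanishing gradient.  Per-feature
standardization across the batch breaks that degeneracy.  Eval-mode
normalization makes every molecule's embedding independent of batch
composition, so checkpointed encodings are deterministic and the
fragment-confinement property below is exact.

## Contrastive channel

Fragment means are pooled from the full-graph node embeddings.  Each
fragment is projected to query/key/value by three learned D×D matrices;
its logit is q·k/√D; the softmax runs over the molecule's own fragments;
the fragment view is the weight-value sum.  Two printed-form ambiguities
are resolved as follows: the attention output applies the scalar softmax
weight to the *value* vector (the composition that is dimensionally
consistent), and the logit is per-fragment rather than one batch-averaged
scalar — a literal batch-mean logit would make the weights uniform within
every molecule and is kept reachable via
`attention_logit_mode="batch_mean"` for comparison.

InfoNCE uses a cosine-similarity critic on the unnormalized pooled
embeddings, no projection head; the denominator includes the positive
term.  Temperature default τ = 0.1, exposed in config.  Batches of size 1
are rejected (no negative).

## Generative channel

Per molecule, ⌊m·n⌋ atoms are masked (at least 1 when n ≥ 2; single-atom
molecules contribute zero loss), default mask ratio m = 0.3 — the midpoint
of the 10–60% range in which the method is reported to be stable.  Masked
atoms' type indices are replaced by the `[MASK]` slot and chirality reset.
The shared encoder then runs with message passing restricted to
intra-fragment bonds, the masked positions' hidden states are re-masked
with a learned decoder token (`remask_before_decode`, default on, so the
decoder must reconstruct from neighbors rather than from the node itself),
and a single GIN decoder layer (also fragment-restricted) plus a linear
head produce the reconstructions.

Targets are the clean atom-feature embeddings (table lookups), *detached*
from the graph: without the stop-gradient the loss could be lowered by
collapsing the embedding tables instead of learning to reconstruct.  The
scaled cosine error (1 − cos)^γ, γ = 2 by default (any γ ≥ 1), is averaged
per molecule and then over the batch.

Fragment confinement: at evaluation, a masked atom's reconstruction
depends only on its own fragment — perturbing features of atoms in other
fragments changes it by exactly zero, because inter-fragment bonds are
removed and eval-mode normalization introduces no cross-node coupling.
During training, batch statistics couple nodes weakly across fragments;
the confinement property is a statement about the operation, verified
bit-for-bit in the tests.

## Pretraining

L = L_C + L_G with no weighting.  Adam (lr 0.001), Glorot initialization,
batch size 256 by default, fixed seed (42 by default) driving
initialization, shuffling and mask sampling; trailing batches smaller than
2 are dropped.  Gradients are clipped to global norm 5.0: the cosine
critic's gradient scales as 1/‖pooled view‖ and the attention-pooled view
can transiently cancel toward zero norm, producing rare spikes an order of
magnitude above the typical gradient that would otherwise throw Adam into
the contrastive collapse saddle.  Non-finite losses abort with a
diagnostic.  Checkpoints (`.npz` + JSON header) carry the config, the
featurization vocabulary sizes, all weights and the normalization buffers;
save → load → encode reproduces embeddings bit-for-bit.

## Fragmentation

BRICS is used in its cut-bond form: the cleavable bonds identified by the
RDKit BRICS rules are deleted and the connected components of the
remainder are the fragments, indexed by smallest contained atom index.
This yields a true partition of the original atom set — required for
fragment pooling and for restricting message passing — whereas BRICS
fragment *enumeration* emits dummy attachment atoms and can overlap.
Multi-component SMILES fragment per component.  A molecule with no
cleavable bond is one fragment.

## Downstream protocol

Scaffold splits group molecules by Bemis–Murcko scaffold (ring-free
molecules share the empty scaffold), order groups by descending size (ties
by first occurrence), and fill train until it holds ≥ 80% of molecules,
then validation until it holds ≥ 10%, remainder test; whole groups only.
Fine-tuning trains encoder + linear head jointly (lr 0.001, dropout 0.5,
sigmoid cross-entropy with missing labels excluded for classification,
squared error for regression), selects the best-validation epoch and
reports the test metric; `freeze_encoder` and a closed-form
`linear_probe` (least squares / logistic regression on frozen embeddings)
cover probing use.  ROC-AUC is rank-based with ties counting 1/2 and is
undefined on single-class inputs (such tasks are skipped with a warning,
as is standard for sparse multi-task panels); the true-positive rate
underlying it is TP/(TP+FN).  RMSE is the root of the mean squared error.
Multi-seed evaluation reports mean ± std across seeds.

## Synthetic libraries

The fixture generator assembles core + linker + tail combinatorially with
linkers (amide, ester, ether) drawn from BRICS-cleavable bond
environments, so essentially every emitted molecule has ≥ 2 fragments and
the fragment channels are exercised.  With `family_labels` it emits two
balanced structural families — aromatic cores (benzene, naphthalene)
versus aliphatic cores (cyclohexane, decalin) — with *identical
heavy-atom composition*, so telling them apart requires bond/connectivity
information rather than atom counts; a continuous companion label tracks
the BRICS fragment count.  Ring-terminated tails diversify the Murcko
scaffolds (≈ 76 groups per 200 molecules) so scaffold splits have many
groups to distribute.

What the generator does not emulate: realistic property distributions,
drug-likeness, stereochemistry-dependent labels, label noise, and the
scale and structural diversity of real pretraining corpora.  Tests passing
on these libraries demonstrate correctness of the machinery and sane
small-scale training dynamics, not benchmark-level transfer.  In
particular the family-probe task is linearly separable by construction,
and at this scale even a randomly initialized encoder's probe can sit at
the ROC-AUC ceiling on the 20-molecule held-out scaffold set, which caps
how much headroom exists for the pretrained-vs-random comparison.

## Desk-scale study conditions

The packaged dynamics checks pretrain on 200 generated molecules for 20
epochs at batch size 64 (the default 256 exceeds the library size; 64
retains 64-way negatives with four steps per epoch).  Under these
conditions the epoch-mean total loss falls by roughly 60–80% depending on
seed, each epoch landing below the mean of all preceding epochs (the
operational reading of "decreasing on average"; a 5-epoch moving-average
monotonicity check also holds on measured runs), and identical seeds
reproduce the final loss exactly.

## Numerical choices and degeneracies

Float64 throughout.  Cosine norms carry a 1e-12 guard; scaled cosine error
raises on zero-norm targets.  Softmaxes subtract detached per-segment or
per-row maxima.  Finite-difference gradient checks hold the detached
reconstruction targets fixed, matching the function the analytic gradient
differentiates.  Empty validation splits abort fine-tuning with an
instruction to adjust ratios; an all-single-class task set raises an
undefined-metric error.

## Known limitations

No 3D conformers, no edge masking or structure reconstruction, no
alternative fragmentation schemes, single-device training only.  The
NumPy engine favors clarity and exact reproducibility over speed; the
default architecture trains at hundreds of molecules per minute on one
CPU core, which is ample for the packaged studies but not for
50K-molecule corpora.
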