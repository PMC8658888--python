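# Methods

## The model

`crnnqsar` builds QSAR models on *molecular latent representations*:
fixed-length real vectors produced by the encoder half of a pretrained
sequence autoencoder from a SMILES string.  The central architecture is a
convolutional-recurrent network (CRNN) that treats the latent vector
**x** ∈ R^d as a length-d, single-channel 1-D signal:

1. three convolution blocks (valid convolution, stride 1) with kernel
   sizes (5, 2, 5) and filter counts (15, 30, 60), each followed by batch
   normalisation and a ReLU (or tanh) activation;
2. one max-pool (window 2, stride 2) after the third block;
3. a single bidirectional GRU over the pooled feature map; the final
   hidden states of the two directions are concatenated;
4. two fully connected layers ending in a 2-unit softmax head
   (classification, cross-entropy loss) or a 1-unit linear head
   (regression, mean-squared-error loss).

The CNN ablation shares the convolutional and dense specification and
replaces the GRU summary with global average pooling over positions.  Two
consequences are intended.  First, the CNN has strictly fewer parameters
than the CRNN (flattening the pooled map into the dense part would invert
that relation, with the first dense layer dwarfing the rest of the
network).  Second, average pooling is *order-invariant*: the CNN can
aggregate what features occur but not where, which makes the CRNN-vs-CNN
contrast a clean probe of global (arrangement) versus local (composition)
feature learning.

Parameters are partitioned into three named groups — `conv`, `gru`,
`dense` — each with its own Adam optimizer learning rate (defaults 1e-4,
5e-4, 1e-4; the dense rate follows the conv rate, which the original
hyperparameter search did not specify separately).  Freezing a group
removes it from the optimizer update loop entirely, so frozen parameters
are bitwise unchanged after any number of steps; the batch-norm running
statistics belong to the conv group's state and are likewise not updated
while that group is frozen.

Inside the GRU, "ReLU activation" is applied to the candidate (body)
activation while the update/reset gates keep their sigmoids — replacing
gate sigmoids abandons the convex-combination semantics of the gated
update.  A `gru_relu_gates` flag exposes the literal gate-and-body
replacement for completeness.

### Numerical core

No deep-learning framework is used: the models run on a compact
reverse-mode autodiff engine over numpy arrays (`crnnqsar.nn`).  The
convolution is evaluated through im2col + BLAS matmuls, and the entire
GRU time loop (forward and backward-through-time) is a single fused graph
node written in plain numpy, which keeps Python per-step overhead out of
the hot path.  Every primitive and the end-to-end models are checked
against central finite differences in the test suite.  Tensors default to
float64; the benchmark harnesses select float32 (`default_dtype`), which
roughly halves runtime and is far below the noise floor of the measured
effects.

## Training protocols

* **Batch size rule** — dataset size ≥ 300 → 128; 101–299 → 64;
  ≤ 100 → 24.
* **Early stopping** — the validation metric (r² for regression, ROC-AUC
  for classification) is monitored after each epoch.  A value more than
  `threshold` (0.005 or 0.01) below the best seen counts as a qualifying
  decrease; a new best resets the counter; training stops at the third
  qualifying decrease.  Decreases need not be consecutive — the
  counter-with-reset reading of "stops after the metric decreases more
  than 2 times".
* **3-phase protocol** (CRNN default) — phase 1 trains `conv`+`dense`
  with the GRU frozen; phase 2 trains the GRU alone; phase 3 trains all
  three groups jointly.  Default phase budgets are 50/50/100 epochs with
  early stopping inside each phase; one Adam instance persists across
  phases so moment estimates are not reset.  The CNN (and the
  from-scratch baseline used in transfer comparisons) trains end-to-end.
* **Grid search** — exhaustive enumeration over user-selected subsets of
  the canonical domains (conv/GRU activations, learning rates
  {1e-3, 5e-4, 1e-4}, 3–5 conv layers, 1–2 GRU layers), deterministic
  first-wins tie-break.

## Evaluation

Random k-fold (k = 5) and grouped k-fold splitting (groups — e.g. isomer
pairs — are never separated; groups are assigned greedily to the
currently smallest fold in seeded random order).  The cluster split runs
k-means (default `max(5, round(n/10))` clusters) and assigns whole
clusters to the test side; a subset-sum selection picks the cluster
combination whose total is as close as possible to the target test
fraction without exceeding it (one extra cluster may exceed it when that
is strictly closer), which keeps the test set inside the training
applicability domain.  ROC-AUC and r² are delegated to scikit-learn /
closed form and are verified against exhaustive pair counting and the
definition in the tests.  Fold metrics aggregate as mean ± standard
error (sample SD / √k).

SMILES-enumeration augmentation expands each *training* molecule to its
canonical SMILES plus 9 randomly enumerated spellings (seeded heavy-atom
renumbering), replicating the label; duplicates among enumerations are
kept, and test partitions are never augmented.

## Transfer learning

A source model is pretrained by 5-fold cross-validation and the best fold
model checkpointed.  Fine-tuning schemes: (1) conv frozen in stage 1,
then full fine-tune; (2) conv frozen throughout; (3) GRU frozen
throughout.  The output head is always reinitialised (source and target
label scales differ).  Stage-2 learning rates can optionally be scaled
down (off by default).  Which source counts as "related" to a target is
the caller's judgement — in the real workflow that comes from external
evidence such as binding-site similarity between assay targets; the
package does not compute such scores.

## Synthetic tasks and the toy encoder

Synthetic items are integer token sequences, not chemically valid SMILES:
that guarantees exact control over composition versus order.  A task's
label combines a *local* score (seed-derived weighted token counts;
permutation-invariant) and a *global* score (position-weighted token
values with centred position weights; changed by almost every
permutation), each z-scored, mixed with the requested weights,
re-standardised, and optionally noised (so r² values are comparable
across specs).  Isomer pairs are a sequence plus a non-identical random
permutation, sharing a group id.  Transfer pairs correlate the *entire*
hidden rule (local, position and token weights) between source and target
with coefficient r — the relatedness knob.  Correlating only the local
weights was tried first and discarded: in latent space the conv/GRU
division of labour does not align with the task's local/global split, and
the freeze-scheme ordering came out inverted.

The toy encoder assigns each (token, position) pair one nonzero latent
coordinate inside a per-position block of dimensions, with a seed-derived
value of magnitude ≥ 1, and embeds a sequence as the mean of its basis
vectors.  The design encodes two premises of the latent-QSAR approach:
sequence-derived latents retain positional structure, and pretrained
latents are feature-ready (no generic decoding stage remains to be
learned).  The second property matters for the transfer experiments: with
a dense random basis, any pretrained network transfers a generic
"decode the encoder" skill to *unrelated* targets, swamping the
rule-similarity effect the experiment is about.  Permutation augmentation
(each training sequence plus random permutations, labels replicated) is
the sequence-world analogue of SMILES enumeration and is label-faithful
exactly on composition-driven tasks.

What the synthetic world does **not** emulate: chemical validity and
grammar of SMILES, the redundancy among enumerated spellings of one
molecule as seen by a real autoencoder, label noise structure of assays,
and activity cliffs.  Passing benchmarks therefore demonstrate the
*mechanisms* (order-feature learning, freeze-based transfer, augmentation
benefit), not chemical accuracy on real assays.

## Benchmark problem sizes

The shipped harnesses (`crnnqsar.benchmarks`) use sequences of length 8
over an 8-token vocabulary with latent dimension 64 — one 8-wide block
per position, so the hidden rule is exactly linearly recoverable from the
latents and headroom between models reflects architecture, not
representation loss.  Harness models use `gru_hidden=32`,
`dense_hidden=64`; phase budgets are 8/6/16 epochs (benchmarks) with
early stopping, 15/10/40 for the small-target from-scratch baselines, and
15+35 for fine-tuning stages.  Sample sizes: n = 2000 for the
global-feature task and transfer sources, 300 for the augmentation task,
150 for transfer targets; five seeds per experiment.  These sizes keep
each experiment in the minutes range on one CPU while leaving the
measured orderings far above seed noise.

## Known limitations

* The GRU-over-latent-dimensions reading of "sequence features of the
  latent" is a modelling assumption; nothing forces a pretrained
  encoder's latent to be position-localized the way the toy encoder is.
* Stacked (2-layer) GRU summaries collapse the intermediate summary to a
  length-1 sequence; the default single layer never takes that path.
* `pretrain_source` selects the best fold by validation metric, which is
  mildly optimistic; the transfer comparisons inherit that bias equally
  across schemes.
* The SVM baseline's inner grid (C, gamma) is a declared stand-in for an
  unpublished protocol in prior work.
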