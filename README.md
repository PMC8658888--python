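# crnnqsar

Quantitative structure–activity relationship (QSAR) modelling on
**molecular latent representations** — the fixed-length vectors a
pretrained sequence autoencoder emits for a SMILES string — using a
convolutional-recurrent network, SMILES-enumeration data augmentation,
and freeze-based transfer learning.

The package is for computational chemists and ML practitioners who want
to (a) model molecular properties or bioactivities from precomputed
latent vectors, (b) probe *why* a sequence-aware model helps — separating
**local** features (which atoms/functional groups are present) from
**global** features (how they are arranged), and (c) transfer knowledge
from a data-rich assay to a data-poor one.

## The model

A latent vector x ∈ R^d is processed as a 1-D signal:

    x → [conv(5)→BN→ReLU] → [conv(2)→BN→ReLU] → [conv(5)→BN→ReLU]
      → maxpool(2) → bidirectional GRU → dense(128) → head

with filter counts 15/30/60, a 2-unit softmax head for classification
(ROC-AUC) or a 1-unit linear head for regression (r²).  The CNN ablation
replaces the GRU with global average pooling — an order-invariant
summary — so the CRNN−CNN performance gap on order-sensitive tasks
measures global-feature learning.  Parameters form three groups
(`conv`/`gru`/`dense`, per-group Adam learning rates 1e-4/5e-4/1e-4);
the 3-phase trainer and the three transfer schemes freeze and unfreeze
these groups exactly (bitwise).

Everything runs on a small numpy reverse-mode autodiff core shipped with
the package — no deep-learning framework is required.

Training protocol highlights:

* batch size by dataset size: ≥300 → 128, 101–299 → 64, ≤100 → 24;
* early stopping on the validation metric: stop at the 3rd drop of more
  than 0.005/0.01 below the best seen, counter reset on a new best;
* 3-phase CRNN training: conv+dense (GRU frozen) → GRU alone → all jointly;
* transfer schemes: conv frozen then full fine-tune / conv frozen
  throughout / GRU frozen throughout, always with a fresh output head.

Because pretrained encoders are deliberately out of scope, the package
includes a deterministic toy sequence encoder (position-localized sparse
basis vectors) and a synthetic task generator whose labels depend
controllably on token composition (local), token order (global), or both
— including exact composition-preserving permutation pairs ("isomers")
and correlated source/target task pairs for transfer experiments.
External latent matrices (e.g. from CDDD-style models) plug in as CSV
keyed by canonical SMILES.

## Worked example

Train/evaluate by 5-fold cross-validation from the command line:

```
$ crnnqsar crossval --model rf --data mols.csv --k 5 --seed 0 --out report.json
{"metric": "r2", "mean": 0.870724360248631, "sem": 0.024990072635861237}
```

Here `mols.csv` is a toy table of 25 alkanes labelled by chain length:
the random forest recovers the label from the fingerprint with a mean
per-fold r² of 0.87 ± 0.02.  The file needs `smiles` and `label` columns; `--model` selects
`crnn`, `cnn`, `augcrnn` (CRNN + tenfold SMILES-enumeration augmentation
of the training folds), `svm` (RBF-SVM on latents) or `rf` (random forest
on ECFP4 fingerprints).  The JSON report holds the per-fold metrics and
their mean ± standard error.

The library surface mirrors this:

```python
from crnnqsar import (SyntheticTaskSpec, make_task, EncoderSpec,
                      CRNNConfig, build_crnn, train_three_phase,
                      r_squared, predict_scores)
from crnnqsar.encoder import encode_sequences

spec = SyntheticTaskSpec(n=2000, seq_len=8, vocab=8, label_mode="global",
                         noise_sd=0.3, seed=1)
task = make_task(spec)                       # order-only labels
enc = EncoderSpec(latent_dim=64, seed=0, max_len=8)
X = encode_sequences(task.sequences, enc).values

cfg = CRNNConfig(latent_dim=64, gru_hidden=32, dense_hidden=64,
                 task="regression")
state = build_crnn(cfg, seed=1)
state, history = train_three_phase(state, (X[:1600], task.labels[:1600]),
                                   (X[1600:], task.labels[1600:]), cfg, seed=1)
print(round(r_squared(task.labels[1600:], predict_scores(state, X[1600:])), 2))
```

This prints `0.86`: the CRNN recovers most of the order-only signal
(the noise-free ceiling is r² ≈ 0.92 at noise_sd 0.3).  Under the same
conditions the CNN ablation stays well below (≈ 0.1–0.4 depending on the
seed) and a composition-count random forest sits at chance (r² ≤ 0) —
order-blind representations cannot see an order-only signal.  That three-way ordering is the mechanism behind the
architecture: the recurrent part adds global-feature extraction while the
convolutional part keeps local-feature extraction intact.

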