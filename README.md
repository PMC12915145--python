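# resbind

Sequence-only prediction of protein binding sites at residue
resolution.  Given nothing but an amino-acid sequence, `resbind`
assigns every residue a probability of being a ligand-binding site —
the same architecture serves any binding-partner class (protein,
peptide, small molecule, carbohydrate, DNA, RNA) by training it on the
corresponding labelled data.  It is aimed at computational biologists
who need binding-site calls for proteins without solved structures,
and at method developers who want a compact, fully deterministic
reference implementation of this model family.

## The model

Residue features from a protein language model (or the shipped
deterministic synthetic embedder) enter a three-part network:

1. **Gated convolutional encoder** — input projection to width
   `d_hid`, then `n` blocks of same-length Conv1D (kernel `k`, padding
   `(k−1)/2`) → GLU (`a ⊙ σ(b)`) → residual scaled by √0.5, with a
   final layer normalisation.  This produces the global sequence
   representation `H_p`.
2. **Cross-attention decoder** — for each residue, a window of `L_l`
   neighbours (projected raw embeddings + learned window position
   embedding) passes through layers of self-attention, multi-head
   cross-attention against `H_p` (`softmax(QKᵀ/√d_k)V`, validity masks
   only, no causal mask), and a position-wise feed-forward net, each
   sublayer in residual + layer norm.
3. **Significance-weighted classifier** — window features are combined
   as `H_agg = Σ_j softmax_j(‖H_j‖)·H_j` and classified by fully
   connected layers (d_hid → 64 → 32 → 2); the binding probability is
   the two-class softmax.

Training minimises class-weighted cross-entropy
`−Σ_i [w·y_i·log ŷ_i + (1−y_i)·log(1−ŷ_i)]` (the rare binding class is
up-weighted, by default with the non-binding/binding ratio) using
RAdam + Lookahead, early stopping on validation MCC with patience 10.
Evaluation covers ACC/precision/recall/F1/MCC/DICE/AUROC/AUPRC, Brier
score with reliability binning, pooled and per-protein scopes, and
mean ± SD aggregation over repeated runs.  A geometric annotation
module builds labels from protein–ligand complexes (6.5 Å / 4.2 Å
distance cutoffs, vdW + 0.5 Å margin rule) and reduces sequence
redundancy by greedy identity clustering.

The network runs on a small built-in numpy autodiff core —
single-threaded, deterministic, no GPU or deep-learning framework
required.  See `docs/methods.md` for assumptions, parameter defaults
and limitations.

## Worked example

Generate a synthetic benchmark with a planted binding rule, train, and
evaluate (Python API; a `resbind` CLI with `simulate` / `annotate` /
`train` / `predict` / `evaluate` subcommands wraps the same calls):

```python
import numpy as np
from resbind import RunConfig, SyntheticEmbedder, train_single
from resbind.synthetic import make_benchmark
from resbind.evaluation import metric_report

train_ds, valid_ds, test_ds, manifest = make_benchmark(
    200, 50, 50, length_range=(50, 150), d_p=64, seed=101)
proteins = train_ds.proteins + valid_ds.proteins
tracks = {**train_ds.tracks, **valid_ds.tracks}
embedder = SyntheticEmbedder(d_p=64, seed=101, noise_sd=0.1)

result = train_single(
    proteins, tracks, embedder, RunConfig(d_hid=64, seed=101),
    tuple(train_ds.ids()), tuple(valid_ds.ids()),
    max_epochs=8, residues_per_protein=48, seed=101)

probs = np.concatenate([result.model.predict_probabilities(test_ds.embeddings[p])
                        for p in test_ds.ids()])
labels = np.concatenate([test_ds.tracks[p].labels for p in test_ds.ids()])
print({k: round(v, 4) for k, v in metric_report(probs, labels).as_dict().items()
       if v is not None})
```

On one CPU this takes a few minutes and prints

```
{'acc': 0.9211, 'precision': 0.6832, 'recall': 0.822, 'auroc': 0.9226,
 'auprc': 0.8403, 'f1': 0.7462, 'mcc': 0.7042, 'dice': 0.7462, 'brier': 0.0664}
```

Reading: the model recovers the planted rule on held-out proteins —
AUROC 0.92 means a randomly chosen binding residue outranks a
non-binding one 92% of the time; MCC 0.70 is high given that only ~12%
of residues are binding sites; the Brier score 0.066 beats the
constant-prevalence baseline (0.121), i.e. the probabilities are
informative, not just the ranking.

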