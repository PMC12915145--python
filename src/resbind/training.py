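"""Weighted cross-entropy training with RAdam + Lookahead and early stopping.

Each residue is an individual sample.  The binding class is rare in
every realistic dataset, so its per-residue loss term is multiplied by
a weight w (default: the non-binding/binding residue ratio of the
training split).  Three training schemes are provided: a single
hold-out split, K-fold selection followed by a retrain on the full
training set, and repeated random splits producing independent models
whose metrics are reported as mean +/- SD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .datamodel import PredictionRow, PredictionTable, ProteinRecord, RunConfig
from .evaluation import confusion, mcc
from .io import split_dataset, kfold_indices, log
from .model import BindingSiteModel

__all__ = [
    "weighted_ce",
    "RAdam",
    "Lookahead",
    "make_optimizer",
    "SchemeSpec",
    "TrainResult",
    "train_single",
    "train",
    "ensemble_predict",
    "grid_search",
]

PROB_CLAMP = 1e-7
DEFAULT_PATIENCE = 10
DEFAULT_MAX_EPOCHS = 100


def weighted_ce(probabilities: Tensor, labels, w: float) -> Tensor:
    """Class-weighted binary cross-entropy, averaged over residues.

    loss = -mean_i [ w * y_i * log(p_i) + (1 - y_i) * log(1 - p_i) ];
    with w = 1 this is the standard binary cross-entropy.
    """
    if w <= 0:
        raise ValueError("loss weight w must be positive")
    y = np.asarray(labels, dtype=probabilities.data.dtype)
    p = probabilities.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    terms = w * y * p.log() + (1.0 - y) * (1.0 - p).log()
    return -terms.mean()


class RAdam:
    """Rectified Adam: adaptive steps gated by the variance-rectification term."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        t = self.t
        b1t, b2t = self.b1 ** t, self.b2 ** t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / (1.0 - b1t)
            if rho_t > 4.0:
                v_hat = np.sqrt(self.v[i] / (1.0 - b2t))
                r = np.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat


class Lookahead:
    """Slow-weight interpolation around an inner optimizer (k steps, alpha)."""

    def __init__(self, inner, k: int = 5, alpha: float = 0.5):
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self.counter = 0
        self.slow = [p.data.copy() for p in inner.params]

    def zero_grad(self):
        self.inner.zero_grad()

    def step(self):
        self.inner.step()
        self.counter += 1
        if self.counter % self.k == 0:
            for slow, p in zip(self.slow, self.inner.params):
                slow += self.alpha * (p.data - slow)
                p.data = slow.copy()


def make_optimizer(params, config: RunConfig, lookahead_k: int = 5, lookahead_alpha: float = 0.5):
    """RAdam wrapped in Lookahead, with the configured learning rate / decay."""
    return Lookahead(
        RAdam(params, lr=config.learning_rate, weight_decay=config.weight_decay),
        k=lookahead_k,
        alpha=lookahead_alpha,
    )


@dataclass
class SchemeSpec:
    """Which of the three training protocols to run."""

    kind: str = "holdout"  # holdout | kfold_then_retrain | repeated_splits
    K: int = 5
    R: int = 10
    valid_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("holdout", "kfold_then_retrain", "repeated_splits"):
            raise ValueError(f"unknown training scheme {self.kind!r}")


@dataclass
class TrainResult:
    model: BindingSiteModel
    report: dict
    best_epoch: int
    best_score: float


def _class_ratio(tracks, ids) -> float:
    pos = sum(tracks[i].n_positive for i in ids)
    neg = sum(tracks[i].n_effective - tracks[i].n_positive for i in ids)
    if pos == 0:
        raise ValueError(
            "training split has no positive residues; check the labels or the split"
        )
    return neg / pos


def _pooled_validation_mcc(model, proteins_by_id, tracks, embeddings, valid_ids,
                          threshold: float) -> float:
    probs, labels = [], []
    for pid in valid_ids:
        p = model.predict_probabilities(embeddings[pid])
        m = tracks[pid].mask.astype(bool)
        probs.append(p[m])
        labels.append(tracks[pid].labels[m])
    probs = np.concatenate(probs)
    labels = np.concatenate(labels)
    return mcc(confusion(probs, labels, threshold))


def train_single(
    proteins,
    tracks: dict,
    embedder,
    config: RunConfig,
    train_ids,
    valid_ids,
    *,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
    fixed_epochs: int | None = None,
    seed: int | None = None,
    validation_scorer=None,
    residues_per_protein: int | None = None,
    dtype=np.float32,
) -> TrainResult:
    """Train one model on ``train_ids`` with early stopping on ``valid_ids``.

    The validation score is pooled MCC at the decision threshold;
    training stops once it fails to improve for ``patience`` epochs and
    the best-epoch weights are restored.  ``fixed_epochs`` disables both
    validation and early stopping (used by the retrain stage of the
    K-fold scheme).  ``validation_scorer(model, epoch) -> float``
    overrides the built-in scorer.  ``residues_per_protein`` caps how
    many (randomly sampled) residues of each protein enter every epoch,
    a computational knob that leaves the objective unbiased.  Training
    runs in single precision by default (``dtype``), the standard
    choice for this class of model.
    """
    proteins_by_id = {p.id: p for p in proteins}
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    w = config.loss_weight if config.loss_weight is not None else _class_ratio(tracks, train_ids)

    embeddings = {pid: embedder(proteins_by_id[pid]) for pid in (*train_ids, *valid_ids)}
    d_p = embeddings[train_ids[0]].dim
    model = BindingSiteModel(config, d_p=d_p, seed=seed, dtype=dtype)
    optimizer = make_optimizer(model.parameters(), config)

    history: list[dict] = []
    best_score, best_epoch = -np.inf, 0
    best_state = model.state_arrays()
    since_best = 0
    n_epochs = fixed_epochs if fixed_epochs is not None else max_epochs

    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(len(train_ids))
        epoch_losses = []
        for idx in order:
            pid = train_ids[idx]
            track = tracks[pid]
            positions = np.flatnonzero(track.mask)
            if positions.size == 0:
                continue
            positions = rng.permutation(positions)
            if residues_per_protein is not None:
                positions = positions[:residues_per_protein]
            for start in range(0, positions.size, config.batch_size):
                batch = positions[start:start + config.batch_size]
                prob, _, _ = model.forward_residues(
                    embeddings[pid], batch, rng=rng, training=True
                )
                loss = weighted_ce(prob, track.labels[batch], w)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_losses.append(float(loss.data))
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}

        if fixed_epochs is None:
            if validation_scorer is not None:
                score = float(validation_scorer(model, epoch))
            else:
                score = _pooled_validation_mcc(
                    model, proteins_by_id, tracks, embeddings, valid_ids,
                    config.decision_threshold,
                )
            record["valid_mcc"] = score
            if score > best_score:
                best_score, best_epoch, since_best = score, epoch, 0
                best_state = model.state_arrays()
            else:
                since_best += 1
            history.append(record)
            log.debug("epoch %d loss %.4f valid_mcc %.4f", epoch, record["train_loss"], score)
            if since_best >= patience:
                break
        else:
            history.append(record)

    if fixed_epochs is None:
        model.load_state_arrays(best_state)
    else:
        best_epoch, best_score = n_epochs, float("nan")
    report = {
        "seed": int(seed),
        "loss_weight": float(w),
        "epochs_run": len(history),
        "best_epoch": int(best_epoch),
        "best_valid_mcc": float(best_score),
        "history": history,
    }
    return TrainResult(model=model, report=report, best_epoch=best_epoch, best_score=best_score)


def train(proteins, tracks, embedder, config: RunConfig, scheme: SchemeSpec, **kwargs):
    """Run one of the three training schemes.

    Returns a single :class:`TrainResult` for ``holdout`` and
    ``kfold_then_retrain``, and a list of results (one per repeat,
    forming an ensemble) for ``repeated_splits``.
    """
    ids = sorted(tracks)
    if scheme.kind == "holdout":
        split = split_dataset(ids, (1.0 - scheme.valid_fraction, scheme.valid_fraction),
                              scheme.seed)
        return train_single(proteins, tracks, embedder, config,
                            split.train_ids, split.valid_ids, seed=scheme.seed, **kwargs)

    if scheme.kind == "kfold_then_retrain":
        folds = kfold_indices(ids, scheme.K, scheme.seed)
        fold_results = [
            train_single(proteins, tracks, embedder, config,
                         fold.train_ids, fold.valid_ids, seed=scheme.seed + k, **kwargs)
            for k, fold in enumerate(folds)
        ]
        epochs = int(round(np.mean([r.best_epoch for r in fold_results])))
        final = train_single(proteins, tracks, embedder, config, tuple(ids), (),
                             fixed_epochs=max(1, epochs), seed=scheme.seed, **kwargs)
        final.report["fold_valid_mcc"] = [r.best_score for r in fold_results]
        return final

    # repeated_splits
    results = []
    for r in range(scheme.R):
        split = split_dataset(ids, (1.0 - scheme.valid_fraction, scheme.valid_fraction),
                              scheme.seed + r)
        results.append(
            train_single(proteins, tracks, embedder, config,
                         split.train_ids, split.valid_ids, seed=scheme.seed + r, **kwargs)
        )
    return results


def ensemble_predict(models, protein: ProteinRecord, embedder,
                     chunk_size: int = 256) -> PredictionTable:
    """Per-residue mean probability across models (order-invariant)."""
    models = list(models)
    if not models:
        raise ValueError("ensemble_predict requires at least one model")
    ref = models[0].config
    for m in models[1:]:
        if m.config.to_dict() != ref.to_dict() or m.d_p != models[0].d_p:
            raise ValueError("ensemble members must share the same configuration")
    stacked = np.mean(
        [m.predict_probabilities(embedder(protein), chunk_size=chunk_size) for m in models],
        axis=0,
    )
    rows = [
        PredictionRow(protein.id, i, protein.sequence[i], float(p),
                      int(p >= ref.decision_threshold))
        for i, p in enumerate(stacked)
    ]
    return PredictionTable(rows)


_GRID_KEYS = ("batch_size", "learning_rate", "dropout_rate", "loss_weight")


def grid_search(proteins, tracks, embedder, base_config: RunConfig, grid: dict,
                scheme: SchemeSpec, **kwargs):
    """Exhaustive search over the four tunables, scored by validation MCC.

    Under the K-fold scheme each grid point is scored by the mean of the
    per-fold best validation MCCs.  Ties break toward the smaller
    learning rate, then the smaller loss weight.  Returns
    ``(best_config, results)`` where results maps grid points to scores.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    unknown = set(grid) - set(_GRID_KEYS)
    if unknown:
        raise ValueError(f"grid keys must be among {_GRID_KEYS}, got extra {sorted(unknown)}")
    keys = sorted(grid)
    ids = sorted(tracks)
    scored = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        config = base_config.replace(**dict(zip(keys, combo)))
        if scheme.kind == "kfold_then_retrain":
            folds = kfold_indices(ids, scheme.K, scheme.seed)
            scores = [
                train_single(proteins, tracks, embedder, config,
                             fold.train_ids, fold.valid_ids, seed=scheme.seed + k,
                             **kwargs).best_score
                for k, fold in enumerate(folds)
            ]
            score = float(np.mean(scores))
        else:
            split = split_dataset(ids, (1.0 - scheme.valid_fraction, scheme.valid_fraction),
                                  scheme.seed)
            score = train_single(proteins, tracks, embedder, config,
                                 split.train_ids, split.valid_ids, seed=scheme.seed,
                                 **kwargs).best_score
        scored.append((config, score))
    effective_w = lambda c: c.loss_weight if c.loss_weight is not None else float("inf")
    best_config, best_score = max(
        scored, key=lambda cs: (cs[1], -cs[0].learning_rate, -effective_w(cs[0]))
    )
    results = [
        {"config": c.to_dict(), "valid_mcc": s} for c, s in scored
    ]
    log.info("grid search best valid_mcc=%.4f", best_score)
    return best_config, results
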