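"""Losses, optimizer steps, the training loop, and fine-tuning.

Training minimizes either softmax cross-entropy (softmax head) or a
one-vs-all multiclass hinge loss (SVM head) with the Adam optimizer at
learning rate 1e-4, batch size 5, for 500 epochs by default — small batches
are deliberate: with an imbalanced class mix, a misclassified rare-class
example carries real weight in a 5-sample batch mean.  Each epoch visits a
fresh seeded uniform permutation of the data; the last short batch is kept.
No data augmentation, no early stopping, no layer freezing during
fine-tuning.

Reproducibility: the loop is bit-reproducible for a fixed seed, data order
and BLAS build (the usual caveat: different BLAS/vendor kernels may round
differently).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset_io import LabeledDataset
from .models import BuiltModel, build_from_spec, load_checkpoint
from .nnops import AdamOptimizer, MomentumOptimizer

__all__ = ["TrainingConfig", "softmax_cross_entropy", "hinge_loss",
           "multiclass_hinge", "adam_step", "train_model", "fine_tune",
           "scheduled_steps"]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 5
    epochs: int = 500
    dropout_p: float = 0.6
    loss: str = "softmax_ce"  # softmax_ce | hinge
    optimizer: str = "adam"  # adam | momentum
    momentum_gamma: float = 0.9
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.loss not in ("softmax_ce", "hinge"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# losses


def softmax_cross_entropy(logits, true_class: int) -> float:
    """-log q(true_class) with q = softmax(logits), max-shifted for stability."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 1:
        raise ValueError("softmax_cross_entropy takes a single logit vector")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    if not 0 <= true_class < logits.shape[0]:
        raise ValueError(f"class index {true_class} out of range")
    z = logits - logits.max()
    return float(np.log(np.exp(z).sum()) - z[true_class])


def _softmax_ce_batch(logits, targets):
    """Mean loss and d(loss)/d(logits) over a batch."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    q = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    losses = -np.log(np.clip(q[np.arange(n), targets], 1e-30, None))
    grad = q.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(losses.mean()), (grad / n).astype(np.float32)


def hinge_loss(score: float, target: int) -> float:
    """Binary hinge l = max(0, 1 - t*y) with t in {-1, +1}."""
    if target not in (-1, 1):
        raise ValueError("hinge target must be +1 or -1")
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return float(max(0.0, 1.0 - target * score))


def multiclass_hinge(scores, true_class: int) -> float:
    """One-vs-all hinge: sum over classes with t=+1 for the true class, -1 else."""
    scores = np.asarray(scores, dtype=np.float64)
    if not 0 <= true_class < scores.shape[-1]:
        raise ValueError(f"class index {true_class} out of range")
    t = -np.ones_like(scores)
    t[true_class] = 1.0
    return float(np.maximum(0.0, 1.0 - t * scores).sum())


def _hinge_batch(scores, targets):
    n, k = scores.shape
    t = -np.ones_like(scores)
    t[np.arange(n), targets] = 1.0
    margins = 1.0 - t * scores
    active = margins > 0
    losses = np.where(active, margins, 0.0).sum(axis=1)
    grad = np.where(active, -t, 0.0) / n
    return float(losses.mean()), grad.astype(np.float32)


# ---------------------------------------------------------------------------
# optimizer steps (functional single-tensor form, used by the oracles/tests;
# the training loop uses the stateful optimizers in nnops)


def adam_step(params, grads, state: dict | None, config: TrainingConfig):
    """One Adam update on a dict of arrays; returns (new_params, new_state).

    Update rule: delta = -lr * m_hat / sqrt(v_hat + eps) with bias-corrected
    moments (the epsilon sits inside the square root).
    """
    b1, b2 = config.adam_beta1, config.adam_beta2
    eps, lr = config.adam_epsilon, config.learning_rate
    if state is None:
        state = {"t": 0,
                 "m": {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()},
                 "v": {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}}
    t = state["t"] + 1
    new_params, new_m, new_v = {}, {}, {}
    for k, p in params.items():
        g = np.asarray(grads[k], dtype=np.float64)
        if g.shape != np.shape(p):
            raise ValueError(f"gradient shape mismatch for {k!r}")
        m = b1 * state["m"][k] + (1 - b1) * g
        v = b2 * state["v"][k] + (1 - b2) * g * g
        mhat = m / (1 - b1 ** t)
        vhat = v / (1 - b2 ** t)
        new_params[k] = p - lr * mhat / np.sqrt(vhat + eps)
        new_m[k], new_v[k] = m, v
    return new_params, {"t": t, "m": new_m, "v": new_v}


def scheduled_steps(n_records: int, epochs: int, batch_size: int) -> int:
    """Total optimizer steps the loop will run: epochs * ceil(n/batch).

    The short final batch of each epoch is kept, so this can exceed
    :func:`equivalent_iterations` when batch_size does not divide n.
    """
    return epochs * (-(-n_records // batch_size))


def equivalent_iterations(n_records: int, epochs: int, batch_size: int) -> int:
    """Full-batch-equivalent iteration count n*epochs/batch — the figure
    conventionally quoted for a training schedule (e.g. 254 images, 4000
    epochs, batch 5 -> 203,200 iterations)."""
    return n_records * epochs // batch_size


# ---------------------------------------------------------------------------
# training loop


def _make_optimizer(config: TrainingConfig):
    if config.optimizer == "adam":
        return AdamOptimizer(lr=config.learning_rate, beta1=config.adam_beta1,
                             beta2=config.adam_beta2, eps=config.adam_epsilon)
    return MomentumOptimizer(lr=config.learning_rate,
                             gamma=config.momentum_gamma)


def train_model(model: BuiltModel, dataset: LabeledDataset,
                config: TrainingConfig) -> tuple[BuiltModel, list[float]]:
    """Train in place; returns (model, per-epoch mean loss trace).

    Expects preprocessed inputs matching the model's input shape.  Fully
    reproducible from ``config.seed`` (shuffling and dropout masks).
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    x = dataset.pixel_stack().astype(np.float32)
    y = dataset.label_indices()
    opt = _make_optimizer(config)
    ss = np.random.SeedSequence(config.seed).spawn(2)
    shuffle_rng = np.random.default_rng(ss[0])
    dropout_rng = np.random.default_rng(ss[1])
    loss_fn = _softmax_ce_batch if config.loss == "softmax_ce" else _hinge_batch
    trace: list[float] = []
    n = len(dataset)
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward_logits(x[idx], train=True, rng=dropout_rng)
            loss, grad = loss_fn(logits.astype(np.float64), y[idx])
            model.net.backward(grad)
            opt.step(model.net)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return model, trace


def fine_tune(pretrained_checkpoint, dataset: LabeledDataset,
              config: TrainingConfig, model: BuiltModel | None = None,
              ) -> tuple[BuiltModel, list[float]]:
    """Continue training from a checkpoint; all layers stay trainable.

    ``model`` must be built from the same architecture spec as the
    checkpoint (default: a fresh canonical W-Net); a spec-hash mismatch in
    the checkpoint raises.  Hyperparameters are the caller's config — in the
    standard protocol identical to from-scratch training except the epochs.
    """
    if model is None:
        from .models import build_wnet
        model = build_wnet()
    load_checkpoint(model, pretrained_checkpoint)
    if config.epochs == 0:
        return model, []
    return train_model(model, dataset, config)
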