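"""Partitioning, augmentation, the staircase learning-rate schedule, class
weighting, Adam training and softmax-only fine-tuning.

Training follows the study protocol: random 75/12.5/12.5 partition into
training / cross-validation / testing, a 25-sample batch, an exponentially
decaying staircase learning rate (initial 1e-4, multiplied by 0.96 every
10,000 steps), class-weighted cross-entropy, and one-time augmentation of
the training volumes by random planar shift, zoom and elastic deformation
(33% of the training set each; never flips or rotations, because map
orientation is anatomically meaningful). Steps are counted in units of
``batch_size`` samples seen, so a 75-epoch run over 13,598 samples at batch
25 amounts to 40,794 update steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .net import Model3DCNN


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 25
    max_epochs: int = 100
    initial_lr: float = 1e-4
    lr_decay_base: float = 0.96
    lr_decay_steps: int = 10_000
    fractions: tuple = (0.75, 0.125, 0.125)
    augment_fraction: float = 0.33      # per transform
    shift_max: float = 0.20             # fraction of the planar extent
    zoom_range: tuple = (0.88, 1.12)
    elastic_magnitude_max: float = 1.0  # displacement magnitude ~ U(0, max), cells
    elastic_sigma: float = 0.08         # Gaussian smoothing SD, relative to extent
    patience: int = 10                  # epochs without val-loss improvement
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


SPLITS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    labels: np.ndarray   # per-trial entries from SPLITS
    level: str           # "trial" or "subject"

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.labels == split)


def partition(n_trials: int, config: TrainConfig,
              subjects: np.ndarray | None = None,
              level: str = "trial",
              class_of_subject: dict | None = None) -> SplitAssignment:
    """Random train/val/test assignment, deterministic given the seed.

    ``level='trial'`` reproduces the study protocol (trials of one subject
    may land in different splits). ``level='subject'`` keeps each subject's
    trials together; it needs at least 3 subjects per class so every split
    can be populated.
    """
    rng = np.random.default_rng(config.seed)
    f_train, f_val, _ = config.fractions
    labels = np.empty(n_trials, dtype=object)
    if level == "trial":
        order = rng.permutation(n_trials)
        n_train = int(np.floor(f_train * n_trials))
        n_val = int(np.floor((f_train + f_val) * n_trials)) - n_train
        labels[order[:n_train]] = "train"
        labels[order[n_train : n_train + n_val]] = "val"
        labels[order[n_train + n_val :]] = "test"
    elif level == "subject":
        if subjects is None:
            raise ValueError("subject-level split needs per-trial subject ids")
        subjects = np.asarray(subjects)
        uniq = np.unique(subjects)
        if class_of_subject is not None:
            from collections import Counter

            counts = Counter(class_of_subject[s] for s in uniq)
            if min(counts.values()) < 3:
                raise ValueError("subject-level split needs >= 3 subjects per class")
        order = rng.permutation(uniq)
        n_s = len(order)
        n_train = int(np.floor(f_train * n_s))
        n_val = int(np.floor((f_train + f_val) * n_s)) - n_train
        split_of = {}
        for i, s in enumerate(order):
            split_of[s] = ("train" if i < n_train
                           else "val" if i < n_train + n_val else "test")
        for i, s in enumerate(subjects):
            labels[i] = split_of[s]
    else:
        raise ValueError("level must be 'trial' or 'subject'")
    return SplitAssignment(labels=labels.astype("U5"), level=level)


# ---------------------------------------------------------------------------
# augmentation (planar only; the frequency axis is never touched)
# ---------------------------------------------------------------------------

def augment_shift(volume: np.ndarray, rng: np.random.Generator,
                  shift_max: float = 0.20, offset: tuple | None = None) -> np.ndarray:
    """Planar translation; offset magnitudes ~ U(0, shift_max * extent) per
    axis with random sign, vacated cells zero-filled. An explicit
    ``offset`` (dx, dy) overrides the random draw."""
    nx, ny = volume.shape[:2]
    if offset is None:
        dx = rng.uniform(0, shift_max * nx) * rng.choice([-1.0, 1.0])
        dy = rng.uniform(0, shift_max * ny) * rng.choice([-1.0, 1.0])
    else:
        dx, dy = offset
    return ndimage.shift(volume, (dx, dy, 0.0), order=1, mode="constant", cval=0.0)


def augment_zoom(volume: np.ndarray, rng: np.random.Generator,
                 zoom_range: tuple = (0.88, 1.12),
                 factor: float | None = None) -> np.ndarray:
    """Planar rescale about the grid centre by a factor ~ U(zoom_range)."""
    if factor is None:
        factor = rng.uniform(*zoom_range)
    nx, ny = volume.shape[:2]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    # output coordinate -> input coordinate: in = centre + (out - centre)/factor
    matrix = np.diag([1.0 / factor, 1.0 / factor, 1.0])
    offset = np.array([cx - cx / factor, cy - cy / factor, 0.0])
    return ndimage.affine_transform(volume, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def augment_elastic(volume: np.ndarray, rng: np.random.Generator,
                    magnitude_max: float = 1.0, sigma: float = 0.08) -> np.ndarray:
    """Smooth random planar displacement field.

    Per-axis white noise on the 20 x 20 plane smoothed with a Gaussian of
    SD ``sigma`` (relative to the grid extent), scaled by a magnitude drawn
    uniformly from [0, magnitude_max] (in cells), applied identically to
    every frequency slice by linear resampling.
    """
    nx, ny, nf = volume.shape
    mag = rng.uniform(0, magnitude_max)
    sig = sigma * nx
    field_x = ndimage.gaussian_filter(rng.standard_normal((nx, ny)), sig)
    field_y = ndimage.gaussian_filter(rng.standard_normal((nx, ny)), sig)

    def _norm(f):
        s = np.abs(f).max()
        return f / s if s > 0 else f

    field_x, field_y = mag * _norm(field_x), mag * _norm(field_y)
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.empty((3, nx, ny, nf))
    coords[0] = (gx + field_x)[..., None]
    coords[1] = (gy + field_y)[..., None]
    coords[2] = np.broadcast_to(np.arange(nf), (nx, ny, nf))
    return ndimage.map_coordinates(volume, coords, order=1, mode="constant", cval=0.0)


def apply_augmentation(volumes: np.ndarray, config: TrainConfig, seed: int,
                       split: str = "train", return_selection: bool = False):
    """One-time augmentation of the training volumes.

    Three independent random subsets of ``floor(augment_fraction * n)``
    volumes are transformed in place (copies) by shift, zoom and elastic
    deformation respectively; the subsets may overlap. Only the training
    split may be augmented.
    """
    if split != "train":
        raise ValueError("augmentation is applied to the training split only")
    rng = np.random.default_rng(seed)
    out = np.array(volumes, copy=True)
    n = len(out)
    n_sel = int(np.floor(config.augment_fraction * n))
    transforms = (
        lambda v: augment_shift(v, rng, config.shift_max),
        lambda v: augment_zoom(v, rng, config.zoom_range),
        lambda v: augment_elastic(v, rng, config.elastic_magnitude_max,
                                  config.elastic_sigma),
    )
    selections = {}
    for name, tf in zip(("shift", "zoom", "elastic"), transforms):
        sel = rng.choice(n, size=n_sel, replace=False)
        selections[name] = np.sort(sel)
        for i in sel:
            out[i] = tf(out[i])
    if return_selection:
        return out, selections
    return out


# ---------------------------------------------------------------------------
# schedule, class weights, training
# ---------------------------------------------------------------------------

def lr_schedule(step: int, config: TrainConfig = TrainConfig()) -> float:
    """Staircase decay: initial_lr * base^floor(step / decay_steps)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return config.initial_lr * config.lr_decay_base ** (step // config.lr_decay_steps)


def total_updates(n_samples: int, batch_size: int, epochs: int) -> int:
    """Update steps for an epoch budget, counting steps in units of
    ``batch_size`` samples seen (partial batches carry over epochs)."""
    return (n_samples * epochs) // batch_size


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights w_c = N / (K * n_c); satisfies
    sum_c n_c w_c = N."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    return counts.sum() / (len(counts) * counts)


class _Adam:
    def __init__(self, params: dict, config: TrainConfig):
        self.cfg = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float, only: set | None = None):
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.adam_beta1**self.t
        b2t = 1.0 - c.adam_beta2**self.t
        for k, g in grads.items():
            if only is not None and k not in only:
                continue
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g**2
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.adam_eps)


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    steps: int = 0
    stopped_early: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": self.epochs, "train_loss": self.train_loss,
             "train_acc": self.train_acc, "val_loss": self.val_loss,
             "val_acc": self.val_acc, "lr": self.lr}
        )


def _evaluate(model, volumes, labels, weights, batch_size=100):
    probs = model.predict_proba(volumes, batch_size=batch_size)
    eps = np.finfo(float).tiny
    wi = weights[labels]
    loss = float(-(wi * np.log(probs[np.arange(len(labels)), labels] + eps)).mean())
    acc = float((probs.argmax(axis=1) == labels).mean())
    return loss + model.penalty(), acc


def train(model: Model3DCNN, train_volumes, train_labels, val_volumes, val_labels,
          config: TrainConfig = TrainConfig(), weights=None,
          trainable: set | None = None, lr_override: float | None = None,
          track_best: bool = False, update_bn: bool = True):
    """Adam training with the staircase schedule and class-weighted loss.

    Stops when the validation loss has not improved for ``patience`` epochs
    or at ``max_epochs``. Returns the model and a :class:`TrainingHistory`;
    with ``track_best`` the weights of the best-validation-loss epoch are
    restored at the end.
    """
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    if weights is None:
        counts = np.bincount(train_labels, minlength=model.spec.n_classes)
        weights = class_weights(counts)
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(config.seed)
    adam = _Adam(model.params, config)
    n = len(train_labels)
    samples_seen = 0
    if track_best:
        # the untouched model is a candidate: fine-tuning can never end
        # worse than it started on the selection metric
        pre_loss, _ = _evaluate(model, val_volumes, val_labels, weights)
        best = (pre_loss, model.state_dict(), -1)
    else:
        best = (np.inf, None, -1)
    since_best = 0
    history = TrainingHistory()
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct, n_batches = 0.0, 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            step = samples_seen // config.batch_size
            lr = lr_override if lr_override is not None else lr_schedule(step, config)
            loss, grads = model.loss_and_grads(
                train_volumes[idx], train_labels[idx], class_weights=weights,
                training=True, rng=rng, update_bn=update_bn,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            adam.step(model.params, grads, lr, only=trainable)
            samples_seen += len(idx)
            ep_loss += loss
            n_batches += 1
        val_loss, val_acc = _evaluate(model, val_volumes, val_labels, weights)
        # training metrics from the running batch averages (no second pass)
        tr_loss = ep_loss / max(1, n_batches)
        tr_acc = float("nan")
        history.epochs.append(epoch)
        history.train_loss.append(tr_loss)
        history.train_acc.append(tr_acc)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.lr.append(lr_schedule(samples_seen // config.batch_size, config)
                          if lr_override is None else lr_override)
        if val_loss < best[0] - 1e-12:
            best = (val_loss, model.state_dict(), epoch)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopped_early = True
                break
    history.steps = samples_seen // config.batch_size
    if track_best and best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def finetune(model: Model3DCNN, train_volumes, train_labels, val_volumes, val_labels,
             lr: float = 2e-5, max_epochs: int = 45,
             config: TrainConfig = TrainConfig(), weights=None):
    """Softmax-only fine-tuning on a new dataset.

    Only the dense (softmax) layer's weights are updated — every other
    parameter is bit-identical before and after — with a low fixed learning
    rate and a limited epoch budget; the returned weights are those of the
    epoch with the best validation loss.
    """
    cfg = replace(config, max_epochs=max_epochs, patience=max_epochs)
    if max_epochs == 0:
        return model, TrainingHistory()
    return train(
        model, train_volumes, train_labels, val_volumes, val_labels, cfg,
        weights=weights, trainable={"dense_W", "dense_b"}, lr_override=lr,
        track_best=True, update_bn=False,
    )
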