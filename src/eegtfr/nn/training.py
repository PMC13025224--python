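"""Fine-tuning loop: AdamW, cosine learning-rate annealing, early stopping
on validation loss with best-checkpoint restore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, cross_entropy, softmax
from .layers import Module

#: ImageNet channel statistics used to normalise input images.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], np.float32)

CLASS_TO_INDEX = {"R": 0, "NR": 1}   # responder is the positive class
INDEX_TO_CLASS = {v: k for k, v in CLASS_TO_INDEX.items()}


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    t_max: int = 8              # cosine annealing period (epochs)
    lr_min: float = 1e-6
    batch_size: int = 32
    max_epochs: int = 8
    patience: int = 3           # early stopping on validation loss
    restore: str = "best"       # "best" = min-val-loss weights, "final" = at stop
    base_seed: int = 42
    fold_index: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.restore not in ("best", "final"):
            raise ValueError("restore must be 'best' or 'final'")

    @property
    def seed(self) -> int:
        return self.base_seed + 100 * self.fold_index


@dataclass
class FoldHistory:
    """Per-epoch training curves for one CV fold."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_val_loss: float = float("inf")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def normalise_images(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 (N, 3, H, W), ImageNet-normalised."""
    x = np.asarray(images, np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def stopped_epoch(val_losses, patience: int) -> int:
    """Epoch count after which the patience rule stops training (1-based).

    Training stops after the first epoch whose loss completes ``patience``
    consecutive epochs without improvement over the running best; returns
    ``len(val_losses)`` if the rule never fires.
    """
    best = float("inf")
    bad = 0
    for i, v in enumerate(val_losses, start=1):
        if v < best:
            best = v
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                return i
    return len(val_losses)


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params, lr, weight_decay, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * self.wd * p.data


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine annealing from lr to lr_min over t_max epochs."""
    frac = min(epoch, cfg.t_max) / cfg.t_max
    return cfg.lr_min + 0.5 * (cfg.lr - cfg.lr_min) * (1 + np.cos(np.pi * frac))


def _eval_split(model: Module, x: np.ndarray, y: np.ndarray, batch: int):
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        xb, yb = x[i:i + batch], y[i:i + batch]
        logits = model(Tensor(xb))
        losses.append(float(cross_entropy(logits, yb).data) * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / len(x), correct / len(x)


def fine_tune(model: Module, train_images: np.ndarray, train_labels: np.ndarray,
              val_images: np.ndarray, val_labels: np.ndarray,
              cfg: TrainConfig | None = None):
    """Train a classifier; returns ``(model, FoldHistory)``.

    Inputs are pre-normalised float32 ``(N, 3, H, W)`` arrays with
    integer class labels (0 = R, 1 = NR).  Training stops when the
    validation loss fails to improve for ``patience`` consecutive
    epochs; depending on ``cfg.restore`` the weights at minimum
    validation loss or at the stopping epoch are kept.  (With very few
    validation subjects the val loss is noisy enough that min-val-loss
    restore can lock in first-epoch weights; ``restore="final"`` is the
    robust choice there.)
    """
    cfg = cfg or TrainConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("both the training and validation splits must be non-empty")
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training split must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), cfg.lr, cfg.weight_decay)
    hist = FoldHistory()
    best_state = model.get_state()
    bad = 0
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cosine_lr(epoch - 1, cfg)
        model.train()
        order = rng.permutation(len(train_images))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = train_images[idx], train_labels[idx]
            model.zero_grad()
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        hist.train_loss.append(sum(losses) / len(order))
        hist.train_acc.append(correct / len(order))

        vl, va = _eval_split(model, val_images, val_labels, cfg.batch_size)
        hist.val_loss.append(vl)
        hist.val_acc.append(va)

        if vl < hist.best_val_loss:
            hist.best_val_loss = vl
            best_state = model.get_state()
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    hist.stopped_epoch = len(hist.train_loss)
    if cfg.restore == "best":
        model.set_state(best_state)
    model.eval()
    return model, hist


def predict(model: Module, images: np.ndarray, batch_size: int = 64):
    """Class indices and softmax probabilities for a batch of images."""
    model.eval()
    probs = []
    for i in range(0, len(images), batch_size):
        logits = model(Tensor(images[i:i + batch_size]))
        probs.append(softmax(Tensor(logits.data), axis=1).data)
    probs = np.concatenate(probs, axis=0) if probs else np.zeros((0, 2))
    return probs.argmax(axis=1), probs
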