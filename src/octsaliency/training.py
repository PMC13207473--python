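"""Training objective and fine-tuning loop for the windowed-attention classifier.

The objective is focal cross-entropy with label smoothing: the smoothed
cross-entropy is modulated per sample by ``(1 - p_t)^gamma`` so easy,
confidently-correct samples contribute less.  Optimisation uses AdamW with
decoupled weight decay and two parameter groups (backbone lr 3e-5, head lr
3e-4), a reduce-on-plateau schedule monitoring validation accuracy, early
stopping, and optional class-balanced sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .backbone import ClassifierModel

__all__ = [
    "TrainConfig",
    "focal_ls_loss",
    "AdamW",
    "ReduceLROnPlateau",
    "train",
]


@dataclass
class TrainConfig:
    lr_backbone: float = 3e-5
    lr_head: float = 3e-4
    weight_decay: float = 1e-4
    focal_gamma: float = 2.0
    label_smoothing: float = 0.05
    max_epochs: int = 100
    min_epochs: int = 10
    plateau_factor: float = 0.5  # cross-validation protocol; 0.8 external
    plateau_patience: int = 3  # cv; 5 external
    early_stop_patience: int = 10  # cv; 12 external
    batch_size: int = 16  # cv; 32 external
    class_balanced_sampler: bool = False
    freeze_backbone: bool = False
    unfreeze_last_n_blocks: int = 20
    seed: int = 56

    def __post_init__(self):
        if self.lr_backbone <= 0 or self.lr_head <= 0:
            raise ValueError("learning rates must be positive")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be >= 0")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label smoothing must lie in [0, 1)")


def focal_ls_loss(
    logits,
    labels,
    gamma: float = 2.0,
    label_smoothing: float = 0.05,
    n_classes: int | None = None,
):
    """Mean focal loss with label smoothing.

    Per sample: ``(1 - p_t)^gamma * CE_smooth`` where ``p = softmax(logits)``,
    ``p_t`` is the true-class probability, and ``CE_smooth`` is cross-entropy
    against ``(1-eps) * onehot + eps/K``.  With ``gamma=0, eps=0`` this is
    exactly standard cross-entropy.

    Accepts a numpy array (returns a float) or an autodiff Tensor (returns a
    scalar Tensor usable for backprop).
    """
    is_tensor = isinstance(logits, Tensor)
    t = logits if is_tensor else Tensor(np.asarray(logits, dtype=np.float64))
    if t.ndim == 1:
        t = t.reshape(1, -1)
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    B, K = t.shape
    if n_classes is None:
        n_classes = K
    if np.any((labels < 0) | (labels >= n_classes)):
        raise ValueError("labels out of range")
    if not np.all(np.isfinite(t.data)):
        raise ValueError("non-finite logits")

    eps = label_smoothing
    q = np.full((B, K), eps / n_classes)
    q[np.arange(B), labels] += 1.0 - eps

    logp = t.log_softmax(axis=-1)
    ce = -(logp * Tensor(q)).sum(axis=-1)  # (B,)
    p_t = logp.take(labels, axis=-1).reshape(B).exp()
    loss = (((1.0 - p_t) ** gamma) * ce).mean() if gamma != 0 else ce.mean()
    return loss if is_tensor else float(loss.data)


class AdamW:
    """AdamW with decoupled weight decay over named parameter groups."""

    def __init__(
        self,
        groups: list[dict],
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        # each group: {"params": {name: Tensor}, "lr": float}
        self.groups = groups
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data) for g in groups for p in g["params"].values()}
        self._v = {id(p): np.zeros_like(p.data) for g in groups for p in g["params"].values()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"].values():
                if p.grad is None:
                    continue
                m = self._m[id(p)] = b1 * self._m[id(p)] + (1 - b1) * p.grad
                v = self._v[id(p)] = b2 * self._v[id(p)] + (1 - b2) * p.grad**2
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data -= lr * self.weight_decay * p.data  # decoupled decay
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"].values():
                p.grad = None


class ReduceLROnPlateau:
    """Maximise-mode plateau scheduler (PyTorch-compatible semantics).

    The learning rate of every group is multiplied by `factor` once the
    monitored metric has failed to improve for more than `patience`
    consecutive epochs after the best one.
    """

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 3,
                 min_lr: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best: float | None = None
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Record one epoch's metric; returns True if the lr was reduced."""
        if self.best is None or metric > self.best:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad > self.patience:
            for g in self.optimizer.groups:
                g["lr"] = max(self.min_lr, g["lr"] * self.factor)
            self.num_bad = 0
            return True
        return False

    @property
    def lrs(self) -> list[float]:
        return [g["lr"] for g in self.optimizer.groups]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr_backbone: list[float] = field(default_factory=list)
    lr_head: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


def _class_balanced_indices(labels: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling with replacement, weight 1/class frequency."""
    classes, counts = np.unique(labels, return_counts=True)
    freq = dict(zip(classes, counts))
    w = np.array([1.0 / freq[y] for y in labels])
    return rng.choice(len(labels), size=n, replace=True, p=w / w.sum())


def train(
    model: ClassifierModel,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Fine-tune `model` in place; returns the per-epoch history.

    If no validation split is given, a stratified 20% tail of the shuffled
    training data is held out internally for the scheduler and early stopping.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty training data")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes present")
    rng = np.random.default_rng(cfg.seed)

    if x_val is None:
        perm = rng.permutation(len(x))
        n_val = max(1, int(0.2 * len(x)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_val, y_val = x[val_idx], y[val_idx]
        x, y = x[tr_idx], y[tr_idx]

    trainable = model.trainable_names(cfg.freeze_backbone, cfg.unfreeze_last_n_blocks)
    bb = {n: model.params[n] for n in model.backbone_param_names() if n in trainable}
    hd = {n: model.params[n] for n in model.head_param_names() if n in trainable}
    opt = AdamW(
        [{"params": bb, "lr": cfg.lr_backbone}, {"params": hd, "lr": cfg.lr_head}],
        weight_decay=cfg.weight_decay,
    )
    sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience)
    hist = TrainHistory()
    best_acc, bad_epochs = -np.inf, 0
    best_state = model.state_dict()

    n = len(x)
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.class_balanced_sampler:
            order = _class_balanced_indices(y, n, rng)
        else:
            order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits, _ = model.forward(xb, training=True, rng=rng)
            loss = focal_ls_loss(
                logits, yb, gamma=cfg.focal_gamma,
                label_smoothing=cfg.label_smoothing, n_classes=model.n_classes,
            )
            opt.zero_grad()
            loss.backward()
            # restrict the update to trainable tensors
            for name, p in model.params.items():
                if name not in trainable:
                    p.grad = None
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=-1) == yb).sum())
        val_acc = float((model.predict(x_val) == y_val).mean())
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(correct / n)
        hist.val_acc.append(val_acc)
        hist.lr_backbone.append(opt.groups[0]["lr"])
        hist.lr_head.append(opt.groups[1]["lr"])
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {hist.train_loss[-1]:.4f}  "
                f"train acc {hist.train_acc[-1]:.3f}  val acc {val_acc:.3f}"
            )
        sched.step(val_acc)
        if val_acc > best_acc:
            best_acc, bad_epochs = val_acc, 0
            best_state = model.state_dict()
        else:
            bad_epochs += 1
        if epoch >= cfg.min_epochs and bad_epochs >= cfg.early_stop_patience:
            hist.stopped_epoch = epoch
            break
    model.load_state_dict(best_state)
    return hist
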