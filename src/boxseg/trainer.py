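"""Offline training of the binary segmentation network on cropped instances.

Instances are sampled one at a time (batch size 1, as crops have varying
shapes) and optimized with SGD with momentum, weight decay and a staircase
learning-rate schedule that halves the rate every ``lr_halving_interval``
iterations.  The loss is the per-pixel cross-entropy of the binary softmax,
averaged over the crop so different crop sizes contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .instance_prep import TrainingInstance
from .networks import Network


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters.

    The full-scale profile (80k iterations, lr 1e-3 halved every 5k) is the
    published recipe; ``desk`` shrinks iterations for laptop-scale runs.
    """

    batch_size: int = 1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    max_iterations: int = 80_000
    initial_lr: float = 1e-3
    lr_halving_interval: int = 5_000
    margin_range: tuple[int, int] = (0, 10)
    val_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.max_iterations, self.lr_halving_interval,
               self.val_interval) < 1:
            raise InputError("batch_size, max_iterations, lr_halving_interval and "
                             "val_interval must be positive")
        if self.initial_lr <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise InputError("initial_lr must be positive; momentum/weight_decay nonnegative")

    @staticmethod
    def desk(max_iterations: int = 2_000, seed: int = 0) -> "TrainConfig":
        return TrainConfig(max_iterations=max_iterations,
                           lr_halving_interval=max(1, max_iterations // 4),
                           seed=seed)


@dataclass
class TrainingLog:
    """Per-iteration training loss and periodic validation loss."""

    train_loss: np.ndarray
    val_iterations: np.ndarray
    val_loss: np.ndarray
    learning_rates: np.ndarray


def learning_rate_at(cfg: TrainConfig, iteration: int) -> float:
    """Staircase schedule; ``iteration`` is 0-based."""
    return cfg.initial_lr * 0.5 ** (iteration // cfg.lr_halving_interval)


def train(net: Network, instances: list[TrainingInstance], cfg: TrainConfig,
          val_instances: list[TrainingInstance] | None = None) -> TrainingLog:
    """SGD training loop; deterministic given ``cfg.seed``.

    Instances must be preprocessed (normalized and resized).  Returns the
    loss curves; the network is updated in place.
    """
    if not instances:
        raise InputError("cannot train on an empty instance list")
    rng = np.random.default_rng(cfg.seed)
    velocity = {k: np.zeros_like(v) for k, v in net.parameters().items()}
    train_loss = np.empty(cfg.max_iterations)
    val_iters, val_losses = [], []
    params = net.parameters()
    for it in range(cfg.max_iterations):
        lr = learning_rate_at(cfg, it)
        idx = int(rng.integers(len(instances)))
        inst = instances[idx]
        loss, grads = net.backprop(inst.region.intensities, inst.mask, reduction="mean")
        train_loss[it] = loss
        for name, g in grads.items():
            v = velocity[name]
            v *= cfg.momentum
            v += g + cfg.weight_decay * params[name]
            params[name] -= (lr * v).astype(params[name].dtype)
        if val_instances and (it + 1) % cfg.val_interval == 0:
            val_iters.append(it + 1)
            val_losses.append(validation_loss(net, val_instances))
    lrs = np.array([learning_rate_at(cfg, it) for it in range(cfg.max_iterations)])
    return TrainingLog(train_loss, np.array(val_iters), np.array(val_losses), lrs)


def validation_loss(net: Network, instances: list[TrainingInstance]) -> float:
    from .networks import softmax_cross_entropy
    total = 0.0
    for inst in instances:
        logits = net.forward_logits(inst.region.intensities)
        loss, _ = softmax_cross_entropy(logits, inst.mask, None, reduction="mean")
        total += loss
    return total / len(instances)


def dice(a, b) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def evaluate(net: Network, instances: list[TrainingInstance]):
    """Per-instance Dice of the thresholded forward pass, plus grouped means.

    Returns ``(scores, by_class)`` where ``by_class`` maps each source
    label to the mean Dice of its instances.
    """
    if not instances:
        raise InputError("cannot evaluate an empty instance list")
    scores = []
    groups: dict = {}
    for inst in instances:
        p = net.forward_probability(inst.region.intensities).p
        d = dice(p > 0.5, inst.mask)
        scores.append(d)
        groups.setdefault(inst.source_label, []).append(d)
    by_class = {k: float(np.mean(v)) for k, v in groups.items()}
    return np.array(scores), by_class
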