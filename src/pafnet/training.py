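"""Training protocol: record-level splits, Gaussian augmentation of
persistent-AF samples, binary cross-entropy with RAdam, and early stopping
on validation accuracy with best-weight restoration.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .records import ValidationError
from .segmentation import EcgSample

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "split_by_recording",
    "augment_gaussian",
    "train",
    "samples_to_arrays",
]


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-3
    early_stop_patience: int = 10       # epochs without val-accuracy improvement
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augment_sigma: float | None = None  # default: 5% of median |R| amplitude
    max_epochs: int = 100
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        if self.early_stop_patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.max_epochs < 0:
            raise ValidationError("max_epochs must be >= 0")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    stopped_epoch: int | None = None


def split_by_recording(record_ids, fractions=(0.8, 0.1, 0.1), seed: int = 0
                       ) -> tuple[set, set, set]:
    """Disjoint, exhaustive, seed-deterministic partition at record level."""
    ids = sorted(set(record_ids))
    if len(ids) < 3:
        raise ValidationError("need at least 3 records to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n = len(perm)
    n_train = int(round(fractions[0] * n))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2)
    return (set(perm[:n_train]),
            set(perm[n_train:n_train + n_val]),
            set(perm[n_train + n_val:]))


def _persistent_af_records(samples: list[EcgSample]) -> set[str]:
    """Records whose every sample is AF (the persistent-AF pattern)."""
    af_count: dict[str, int] = defaultdict(int)
    total: dict[str, int] = defaultdict(int)
    for s in samples:
        total[s.record_id] += 1
        af_count[s.record_id] += bool(s.label)
    return {rid for rid in total if af_count[rid] == total[rid]}


def augment_gaussian(samples: list[EcgSample], sigma: float, seed: int = 0
                     ) -> list[EcgSample]:
    """Originals plus Gaussian-noised copies of persistent-AF samples.

    Only AF samples from records that are AF throughout are duplicated;
    labels are unchanged and the draw is seed-deterministic.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    persistent = _persistent_af_records(samples)
    out = list(samples)
    for s in samples:
        if s.label and s.record_id in persistent:
            noisy = s.values + rng.normal(0.0, sigma, size=s.values.shape
                                          ).astype(s.values.dtype)
            out.append(EcgSample(noisy, s.label, s.start_beat,
                                 s.record_id, s.channel))
    return out


def default_augment_sigma(samples: list[EcgSample]) -> float:
    """5% of the corpus' median per-sample peak amplitude."""
    if not samples:
        return 0.0
    peaks = [float(np.max(np.abs(s.values))) for s in samples]
    return 0.05 * float(np.median(peaks))


def samples_to_arrays(samples: list[EcgSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.values for s in samples]).astype(np.float32)[:, :, None]
    y = np.asarray([s.label for s in samples], dtype=np.float32)
    return x, y


def _accuracy(network: nn.Network, x: np.ndarray, y: np.ndarray,
              threshold: float, batch_size: int = 256) -> float:
    probs = network.predict_proba(x, batch_size).ravel()
    return float(np.mean((probs >= threshold) == (y > 0.5)))


def train(network: nn.Network,
          train_samples: list[EcgSample],
          val_samples: list[EcgSample],
          config: TrainConfig) -> TrainingHistory:
    """Minimize BCE with RAdam; early-stop on validation accuracy.

    Stops when validation accuracy has not improved for
    ``early_stop_patience`` consecutive epochs (or at ``max_epochs``) and
    restores the best-validation weights.
    """
    config.validate()
    history = TrainingHistory()
    if config.max_epochs == 0:
        return history
    x_tr, y_tr = samples_to_arrays(train_samples)
    x_va, y_va = samples_to_arrays(val_samples)
    if len(np.unique(y_tr)) < 2:
        raise ValidationError("training set contains a single class")

    rng = np.random.default_rng(config.seed)
    opt = nn.RAdam(network.trainable_params(), lr=config.learning_rate)
    best_acc, best_state, since_best = -np.inf, None, 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        losses, correct = [], 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            network.zero_grad()
            logits = network.forward(xb, training=True)
            losses.append(nn.bce_with_logits(logits, yb))
            network.backward(nn.bce_with_logits_grad(logits, yb))
            opt.step()
            correct += int(np.sum((nn.sigmoid(logits).ravel() >= config.threshold)
                                  == (yb > 0.5)))
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / len(x_tr))
        val_acc = _accuracy(network, x_va, y_va, config.threshold)
        history.val_accuracy.append(val_acc)

        if val_acc > best_acc:
            best_acc, since_best = val_acc, 0
            best_state = network.state_dict()
            history.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                history.stopped_epoch = epoch
                break
    if best_state is not None:
        network.load_state_dict(best_state)
    return history


def simulate_early_stopping(val_accuracies: list[float], patience: int
                            ) -> tuple[int | None, int | None]:
    """(best_epoch, stopped_epoch) the early-stopping rule would produce on
    a scripted validation-accuracy sequence (1-based epochs)."""
    best, best_epoch, since = -np.inf, None, 0
    for epoch, acc in enumerate(val_accuracies, start=1):
        if acc > best:
            best, best_epoch, since = acc, epoch, 0
        else:
            since += 1
            if since >= patience:
                return best_epoch, epoch
    return best_epoch, None
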