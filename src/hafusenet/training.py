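"""Training loop, loss, and the two evaluation protocols.

Training follows the target-dataset recipe: Adam at learning rate 1e-3
with weight-decay 5e-3, batch size 32, a fixed number of epochs (300
for the benchmark; desk-scale runs use fewer) and no validation split
or early stopping.  The loss is categorical cross-entropy computed in a
numerically stable log-sum-exp form on the model's class scores.

Within-subject protocol: one model per subject, trained on that
subject's training session and tested on its evaluation session.
Cross-subject (leave-one-subject-out) protocol: for each subject i the
training sessions of all other subjects are pooled
(Train_i = sum_{j != i} Train_j) and subject i's evaluation session is
the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np

from .metrics import accuracy, confusion_matrix, kappa
from .models import HAFuseNet
from .nn import Adam, Tensor
from .types import EpochSet, MetricsReport

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "train",
    "evaluate",
    "concat_epochsets",
    "build_loso_pool",
    "within_subject_protocol",
    "cross_subject_protocol",
]


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 300
    learning_rate: float = 1e-3
    weight_decay: float = 5e-3
    seed: int = 0
    val_fraction: float = 0.0  # no validation split by default

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("training parameters must be positive")


def _batch_loss(model: HAFuseNet, xb: np.ndarray, yb: np.ndarray) -> tuple[Tensor, int]:
    z = model.logits(Tensor(xb))
    m = Tensor(z.data.max(axis=1, keepdims=True))
    lse = m.reshape(-1) + ((z - m).exp().sum(axis=1)).log()
    onehot = np.zeros(z.shape, dtype=np.float32)
    onehot[np.arange(len(yb)), yb] = 1.0
    z_true = (z * Tensor(onehot)).sum(axis=1)
    loss = (lse - z_true).mean()
    n_correct = int((z.data.argmax(axis=1) == yb).sum())
    return loss, n_correct


def train(
    model: HAFuseNet, epochs: EpochSet, cfg: TrainConfig
) -> tuple[HAFuseNet, dict]:
    """Minibatch training; returns the model and a per-epoch history."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    x = epochs.data
    y = epochs.labels
    n_val = int(round(cfg.val_fraction * len(y)))
    if n_val:
        perm = rng.permutation(len(y))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_val, y_val = x[val_idx], y[val_idx]
        x, y = x[tr_idx], y[tr_idx]
    history: dict = {"loss": [], "accuracy": []}
    if n_val:
        history["val_accuracy"] = []

    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y))
        total_loss, total_correct = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            loss, n_correct = _batch_loss(model, x[idx], y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * len(idx)
            total_correct += n_correct
        history["loss"].append(total_loss / len(y))
        history["accuracy"].append(total_correct / len(y))
        if n_val:
            cm = evaluate(model, EpochSet(x_val, y_val, epochs.sampling_rate), cfg.batch_size)
            history["val_accuracy"].append(accuracy(cm))
            model.train()
    model.eval()
    return model, history


def evaluate(model: HAFuseNet, epochs: EpochSet, batch_size: int = 64) -> np.ndarray:
    """Confusion matrix of the model's predictions on an epoch set."""
    model.eval()
    preds = []
    for lo in range(0, epochs.n_trials, batch_size):
        probs = model(Tensor(epochs.data[lo : lo + batch_size]))
        preds.append(probs.data.argmax(axis=1))
    preds = np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)
    n_classes = model.cfg.disnet.n_classes
    return confusion_matrix(epochs.labels, preds, n_classes=n_classes)


def concat_epochsets(sets: list[EpochSet]) -> EpochSet:
    if not sets:
        raise ValueError("nothing to concatenate")
    return replace(
        sets[0],
        data=np.concatenate([s.data for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets], axis=0),
        subject_id="+".join(s.subject_id for s in sets),
    )


def build_loso_pool(
    data: Mapping[str, Mapping[str, EpochSet]], held_out: str
) -> EpochSet:
    """Union of all other subjects' training sessions, in subject order."""
    others = [data[s]["T"] for s in sorted(data) if s != held_out]
    if not others:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    return concat_epochsets(others)


def _run_protocol(
    pairs: list[tuple[str, EpochSet, EpochSet]],
    model_factory: Callable[[int], HAFuseNet],
    train_cfg: TrainConfig,
) -> MetricsReport:
    report = MetricsReport()
    for i, (subject, train_set, test_set) in enumerate(pairs):
        model = model_factory(train_cfg.seed + i)
        cfg_i = replace(train_cfg, seed=train_cfg.seed + i)
        model, _ = train(model, train_set, cfg_i)
        cm = evaluate(model, test_set, batch_size=train_cfg.batch_size)
        report.confusion[subject] = cm
        report.accuracy[subject] = accuracy(cm)
        report.kappa[subject] = kappa(cm)
        logger.info(
            "subject %s: accuracy %.3f kappa %.3f",
            subject,
            report.accuracy[subject],
            report.kappa[subject],
        )
    return report


def within_subject_protocol(
    data: Mapping[str, Mapping[str, EpochSet]],
    model_factory: Callable[[int], HAFuseNet],
    train_cfg: TrainConfig,
) -> MetricsReport:
    """One independent model per subject: train on session T, test on E."""
    pairs = []
    for subject in sorted(data):
        sessions = data[subject]
        if "T" not in sessions or "E" not in sessions:
            raise ValueError(f"subject {subject!r} is missing a T or E session")
        pairs.append((subject, sessions["T"], sessions["E"]))
    return _run_protocol(pairs, model_factory, train_cfg)


def cross_subject_protocol(
    data: Mapping[str, Mapping[str, EpochSet]],
    model_factory: Callable[[int], HAFuseNet],
    train_cfg: TrainConfig,
) -> MetricsReport:
    """Leave-one-subject-out: train on the other subjects' pooled T sessions."""
    if len(data) < 2:
        raise ValueError("cross-subject protocol needs at least two subjects")
    pairs = []
    for subject in sorted(data):
        if "E" not in data[subject]:
            raise ValueError(f"subject {subject!r} is missing an E session")
        pairs.append((subject, build_loso_pool(data, subject), data[subject]["E"]))
    return _run_protocol(pairs, model_factory, train_cfg)
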