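"""Training protocol: stratified k-fold cross-validation with Adam,
reduce-on-plateau learning-rate schedule, and best-validation checkpointing.

Defaults follow the published protocol: initial learning rate 0.0005,
decayed by a factor of 0.1 when the validation accuracy has not improved
for 10 epochs, mini-batches of 100, cross-entropy loss, and for every fold
the checkpoint with the best validation accuracy is the evaluated model.
A stratified 10% slice of each fold's training data serves as the
validation set; the held-out test fold is never seen before evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split

from .io import EvalReport, SegmentTable
from .metrics import task_score
from .network import ArchitectureSpec, MNLNetwork, build_model
from .nn.optim import Adam
from .preprocessing import TaskScheme, build_task_dataset, parse_scheme

__all__ = ["TrainConfig", "FoldSplit", "make_folds", "train_fold",
           "evaluate", "cross_validate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    lr_decay_factor: float = 0.1
    plateau_patience_epochs: int = 10
    batch_size: int = 100
    max_epochs: int = 100
    seed: int = 0
    val_fraction: float = 0.1
    min_lr: float = 1e-7            # training stops once lr decays below this
    device: str = "cpu"

    def __post_init__(self):
        if not 0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class FoldSplit:
    k: int
    test_indices: list[np.ndarray]
    class_counts: dict = field(default_factory=dict)  # class -> per-fold counts

    def train_indices(self, fold: int) -> np.ndarray:
        return np.concatenate([idx for i, idx in enumerate(self.test_indices)
                               if i != fold])


def make_folds(dataset: SegmentTable, k: int = 10, seed: int = 0) -> FoldSplit:
    """Stratified k-fold partition: each class contributes equal counts to
    each fold (+/-1 when not divisible). Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    per_fold: list[list[np.ndarray]] = [[] for _ in range(k)]
    class_counts = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} segments, fewer than k={k}")
        rng.shuffle(idx)
        parts = np.array_split(idx, k)
        for f, part in enumerate(parts):
            per_fold[f].append(part)
        class_counts[int(cls)] = [len(p) for p in parts]
    test_indices = [np.sort(np.concatenate(parts)) for parts in per_fold]
    return FoldSplit(k=k, test_indices=test_indices, class_counts=class_counts)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_fold(model: MNLNetwork, train_x: np.ndarray, train_y: np.ndarray,
               config: TrainConfig) -> tuple[dict, dict]:
    """Train one model; returns (best checkpoint state, history).

    History holds per-epoch training loss, validation accuracy, and the
    learning rate in force.
    """
    if len(train_x) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    tr_x, va_x, tr_y, va_y = train_test_split(
        train_x, train_y, test_size=config.val_fraction,
        stratify=train_y, random_state=config.seed % (2 ** 32))
    for cls in np.unique(train_y):
        if not np.any(va_y == cls):
            raise ValueError(f"validation slice empty for class {cls}")
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = {"loss": [], "val_accuracy": [], "lr": []}
    best = {"val_accuracy": -1.0, "epoch": -1, "state": None}
    epochs_since_improvement = 0
    for epoch in range(config.max_epochs):
        losses = []
        for batch_idx in _iter_batches(len(tr_x), config.batch_size, rng):
            optimizer.zero_grad()
            losses.append(model.train_step_loss(tr_x[batch_idx], tr_y[batch_idx]))
            optimizer.step()
        val_acc = float(np.mean(model.predict(va_x) == va_y))
        history["loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        history["lr"].append(optimizer.lr)
        if val_acc > best["val_accuracy"]:
            best = {"val_accuracy": val_acc, "epoch": epoch,
                    "state": model.get_state()}
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement >= config.plateau_patience_epochs:
                optimizer.lr *= config.lr_decay_factor
                epochs_since_improvement = 0  # schedule re-arms
                logger.info("epoch %d: plateau, lr -> %.2e", epoch, optimizer.lr)
                if optimizer.lr < config.min_lr:
                    logger.info("lr below %.1e, stopping early", config.min_lr)
                    break
    history["best_epoch"] = best["epoch"]
    history["best_val_accuracy"] = best["val_accuracy"]
    return best["state"], history


def evaluate(model: MNLNetwork, x: np.ndarray, y: np.ndarray,
             n_classes: int) -> dict[str, float]:
    return task_score(y, model.predict(x), n_classes)


def cross_validate(segments: SegmentTable, scheme: TaskScheme | str,
                   config: TrainConfig | None = None, k: int = 10,
                   arch: ArchitectureSpec | None = None,
                   return_histories: bool = False):
    """Full k-fold protocol for one class-combination task.

    For each fold a fresh model is trained on the other k-1 folds (with a
    stratified validation carve-out) and its best checkpoint is evaluated on
    the held-out fold; the report lists per-fold metrics and their mean.
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    config = config or TrainConfig()
    dataset = build_task_dataset(segments, scheme)
    if arch is None:
        arch = ArchitectureSpec(input_length=dataset.segment_length,
                                n_classes=scheme.n_classes)
    elif arch.n_classes != scheme.n_classes:
        arch = replace(arch, n_classes=scheme.n_classes)
    folds = make_folds(dataset, k=k, seed=config.seed)
    report = EvalReport(scheme=scheme.scheme_string, k=k)
    histories = []
    all_idx = np.sort(np.concatenate(folds.test_indices))
    assert len(all_idx) == len(dataset) and len(np.unique(all_idx)) == len(dataset)
    for fold in range(k):
        test_idx = folds.test_indices[fold]
        train_idx = folds.train_indices(fold)
        assert len(np.intersect1d(test_idx, train_idx)) == 0, "fold leakage"
        fold_seed = int(np.random.SeedSequence(
            config.seed, spawn_key=(2, fold)).generate_state(1)[0] % (2 ** 31))
        model = build_model(arch, seed=fold_seed)
        state, history = train_fold(
            model, dataset.segments[train_idx], dataset.labels[train_idx],
            replace(config, seed=fold_seed))
        model.set_state(state)
        fold_metrics = evaluate(model, dataset.segments[test_idx],
                                dataset.labels[test_idx], scheme.n_classes)
        logger.info("fold %d: accuracy %.4f", fold + 1, fold_metrics["accuracy"])
        report.add_fold(fold_metrics)
        histories.append(history)
    report.validate()
    if return_histories:
        return report, histories
    return report
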