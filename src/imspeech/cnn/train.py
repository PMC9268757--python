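"""Training protocol: stratified k-fold over the train split, fixed test set.

Each fold trains on the other k−1 folds (75% of the train split when k = 4),
uses the held-out fold as the validation set for early stopping, and is then
scored on the fixed test split; the grid tables report the per-fold test
loss/accuracy as mean ± standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ..features import FeatureMatrix
from ..io import PROMPTS, encode_prompt
from .arch import ArchSpec
from .network import SequentialCNN, build_model

__all__ = ["TrainConfig", "TrainResult", "features_to_arrays",
           "train_kfold", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the study protocol: Adam at learning rate 1e-4,
    categorical cross-entropy, 4 folds (so each fold validates on 25% of the
    train split), batches of 32, up to ``epochs`` epochs with early stopping
    on validation loss.
    """

    learning_rate: float = 1e-4
    k_folds: int = 4
    epochs: int = 50
    batch_size: int = 32
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.k_folds < 2:
            raise ValueError("need at least 2 folds")

    @property
    def val_fraction(self) -> float:
        """Validation share of the train split, 1/k (0.25 for k = 4)."""
        return 1.0 / self.k_folds


@dataclass
class TrainResult:
    """Per-fold test (loss, accuracy) with their mean ± population std."""

    per_fold: list[tuple[float, float]]
    models: list[SequentialCNN]
    fold_indices: list[np.ndarray]

    @property
    def losses(self) -> np.ndarray:
        return np.array([l for l, _ in self.per_fold])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([a for _, a in self.per_fold])

    @property
    def mean_loss(self) -> float:
        return float(self.losses.mean())

    @property
    def std_loss(self) -> float:
        return float(self.losses.std())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std())


def features_to_arrays(mats: Sequence[FeatureMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature matrices into (N, C, C) float32 X and int label vector y."""
    if not mats:
        raise ValueError("empty feature list")
    x = np.stack([m.values for m in mats]).astype(np.float32)
    y = np.array([encode_prompt(m.label) for m in mats], dtype=np.int64)
    return x, y


def train_kfold(train_feats: Sequence[FeatureMatrix],
                test_feats: Sequence[FeatureMatrix],
                arch: ArchSpec,
                cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Stratified k-fold training on the train split, scored on the test split.

    The train split is partitioned into ``cfg.k_folds`` class-stratified
    folds (seeded).  For fold i a fresh network trains on the other folds
    with fold i as validation, then its loss/accuracy on the fixed ``test``
    split is recorded.  Test windows must be disjoint from training windows
    by origin.
    """
    x_train, y_train = features_to_arrays(train_feats)
    x_test, y_test = features_to_arrays(test_feats)
    train_origins = {m.origin for m in train_feats}
    overlap = train_origins & {m.origin for m in test_feats}
    if overlap:
        raise ValueError(f"test windows overlap train split: {sorted(overlap)[:3]}")
    counts = np.bincount(y_train, minlength=len(PROMPTS))
    present = counts[counts > 0]
    if present.min() < 2:
        raise ValueError("every class present in training needs ≥ 2 examples")
    if cfg.k_folds > present.min():
        raise ValueError(
            f"k_folds={cfg.k_folds} exceeds the smallest class count "
            f"{present.min()}"
        )
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                          random_state=cfg.seed)
    per_fold: list[tuple[float, float]] = []
    models: list[SequentialCNN] = []
    fold_indices: list[np.ndarray] = []
    for fold, (fit_idx, val_idx) in enumerate(skf.split(x_train, y_train)):
        model = build_model(arch, x_train.shape[1],
                            seed=(cfg.seed + 1000003 * (fold + 1)) % (2 ** 31))
        model.fit(
            x_train[fit_idx], y_train[fit_idx],
            x_train[val_idx], y_train[val_idx],
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, patience=cfg.patience,
            seed=(cfg.seed + 7919 * (fold + 1)) % (2 ** 31),
        )
        per_fold.append(model.evaluate(x_test, y_test))
        models.append(model)
        fold_indices.append(val_idx)
    return TrainResult(per_fold=per_fold, models=models,
                       fold_indices=fold_indices)


def predict(model: SequentialCNN,
            mats: Sequence[FeatureMatrix],
            class_names: Sequence[str] = PROMPTS) -> list[tuple[str, np.ndarray]]:
    """Predicted label and probability vector per feature matrix.

    The label is the argmax of the softmax vector; exact ties break toward
    the lower class index.  Output order follows the input order.
    """
    x = np.stack([m.values for m in mats]).astype(np.float32)
    proba = model.predict_proba(x)
    idx = proba.argmax(axis=1)  # np.argmax returns the first (lowest) maximum
    return [(class_names[i], p) for i, p in zip(idx, proba)]
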