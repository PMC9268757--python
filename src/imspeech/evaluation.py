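"""Classification metrics and the experiment-grid runner.

Metrics are computed per fold from the fold model's predictions on the fixed
test split, then averaged (mean ± population standard deviation across
folds); confusion matrices are averaged entrywise.  The grid runner sweeps
feature domain × window length × smoothing kernel × conv activation ×
architecture, reusing one windowing/split per window length so that feature
comparisons see identical window assignments.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnn import ArchSpec, TrainConfig, TrainResult, parse_arch, train_kfold
from .features import (FeatureMatrix, SmoothingKernel, ccv_frequency, ccv_time,
                       standardize_features)
from .io import PROMPTS, Recording, encode_prompt
from .preprocess import (EpochWindow, SplitSpec, WindowSpec, segment_windows,
                         split_train_test)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "GridResult",
    "confusion_matrix",
    "accuracy",
    "balanced_accuracy",
    "macro_recall",
    "cohens_kappa",
    "mean_fold_report",
    "evaluate_folds",
    "run_grid",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = PROMPTS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        n = len(self.class_names)
        if counts.shape != (n, n):
            raise ValueError(f"expected {n}×{n} counts, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Per-class number of true examples (row sums)."""
        return self.counts.sum(axis=1)


def confusion_matrix(truth: Sequence[str], pred: Sequence[str],
                     class_names: Sequence[str] = PROMPTS) -> ConfusionMatrix:
    """Tally counts[i, j] = #{t : truth_t = class i, pred_t = class j}."""
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    if len(truth) == 0:
        raise ValueError("need at least one prediction")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def _per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    supports = cm.supports
    present = supports > 0
    if not present.any():
        raise ValueError("all class supports are zero")
    if not present.all():
        absent = [cm.class_names[i] for i in np.flatnonzero(~present)]
        logger.warning("classes without support excluded from recall: %s",
                       absent)
    diag = np.diag(cm.counts)[present]
    return diag / supports[present]


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls (classes with support only)."""
    return float(_per_class_recall(cm).mean())


def macro_recall(cm: ConfusionMatrix) -> float:
    """Macro-averaged recall; identical to balanced accuracy by definition,
    kept as its own named metric to match reporting conventions."""
    return float(_per_class_recall(cm).mean())


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    row = cm.counts.sum(axis=1) / total
    col = cm.counts.sum(axis=0) / total
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-15:
        raise ValueError("degenerate marginals: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def _mean_std(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=np.float64)
    return float(arr.mean()), float(arr.std())  # population std over folds


@dataclass(frozen=True)
class MetricsReport:
    """Fold-averaged metrics (mean, std) and the entrywise-mean confusion matrix."""

    accuracy: tuple[float, float]
    balanced_accuracy: tuple[float, float]
    kappa: tuple[float, float]
    macro_recall: tuple[float, float]
    mean_confusion: np.ndarray
    loss: tuple[float, float] | None = None

    def confusion_frame(self, class_names: Sequence[str] = PROMPTS) -> pd.DataFrame:
        """Mean confusion matrix as a labelled DataFrame (rows = truth)."""
        n = self.mean_confusion.shape[0]
        names = list(class_names)[:n]
        return pd.DataFrame(self.mean_confusion, index=names, columns=names)

    def save_confusion(self, path, class_names: Sequence[str] = PROMPTS):
        """Write the mean confusion matrix as CSV and a heatmap PNG."""
        from pathlib import Path

        path = Path(path)
        frame = self.confusion_frame(class_names)
        frame.to_csv(path.with_suffix(".csv"))
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(frame.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(frame)), frame.columns, rotation=90,
                      fontsize=7)
        ax.set_yticks(range(len(frame)), frame.index, fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax, label="mean count over folds")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=150)
        plt.close(fig)
        return path.with_suffix(".csv")

    def summary(self) -> str:
        parts = [f"accuracy {self.accuracy[0]:.4f} ± {self.accuracy[1]:.4f}",
                 f"balanced {self.balanced_accuracy[0]:.4f} ± {self.balanced_accuracy[1]:.4f}",
                 f"kappa {self.kappa[0]:.4f} ± {self.kappa[1]:.4f}",
                 f"recall {self.macro_recall[0]:.4f} ± {self.macro_recall[1]:.4f}"]
        if self.loss is not None:
            parts.insert(0, f"loss {self.loss[0]:.4f} ± {self.loss[1]:.4f}")
        return ", ".join(parts)


def mean_fold_report(fold_cms: Sequence[ConfusionMatrix],
                     fold_losses: Sequence[float] | None = None) -> MetricsReport:
    """Per-fold metrics averaged with std; confusion matrix averaged entrywise."""
    if not fold_cms:
        raise ValueError("need at least one fold")
    return MetricsReport(
        accuracy=_mean_std([accuracy(cm) for cm in fold_cms]),
        balanced_accuracy=_mean_std([balanced_accuracy(cm) for cm in fold_cms]),
        kappa=_mean_std([cohens_kappa(cm) for cm in fold_cms]),
        macro_recall=_mean_std([macro_recall(cm) for cm in fold_cms]),
        mean_confusion=np.mean([cm.counts for cm in fold_cms], axis=0),
        loss=None if fold_losses is None else _mean_std(fold_losses),
    )


def evaluate_folds(result: TrainResult,
                   test_feats: Sequence[FeatureMatrix]) -> MetricsReport:
    """Score every fold model on the fixed test split and fold-average."""
    from .cnn import features_to_arrays

    x_test, y_test = features_to_arrays(test_feats)
    truth = [m.label for m in test_feats]
    fold_preds = [
        [PROMPTS[i] for i in model.predict_proba(x_test).argmax(axis=1)]
        for model in result.models
    ]
    # confusion axes cover the classes that actually occur (truth or
    # prediction, any fold), in prompt-encoding order
    seen = set(truth).union(*map(set, fold_preds))
    classes = tuple(p for p in PROMPTS if p in seen)
    cms = [confusion_matrix(truth, preds, class_names=classes)
           for preds in fold_preds]
    return mean_fold_report(cms, fold_losses=list(result.losses))


# ---------------------------------------------------------------------------
# grid runner


@dataclass
class GridResult:
    """Metrics per grid cell, keyed by (domain, window, kernel, activation, arch)."""

    cells: dict[tuple, MetricsReport]
    errors: dict[tuple, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per requested combination; failed cells keep an error note.

        Within each (domain, window, kernel, activation) condition the best
        architecture by mean accuracy is flagged.
        """
        rows = []
        for key, rep in self.cells.items():
            domain, window, kernel, activation, arch = key
            rows.append({
                "domain": domain, "window_s": window, "kernel": kernel,
                "activation": activation, "arch": arch,
                "loss_mean": rep.loss[0] if rep.loss else np.nan,
                "loss_std": rep.loss[1] if rep.loss else np.nan,
                "accuracy_mean": rep.accuracy[0],
                "accuracy_std": rep.accuracy[1],
                "balanced_accuracy_mean": rep.balanced_accuracy[0],
                "kappa_mean": rep.kappa[0],
                "macro_recall_mean": rep.macro_recall[0],
                "error": "",
            })
        for key, msg in self.errors.items():
            domain, window, kernel, activation, arch = key
            rows.append({"domain": domain, "window_s": window,
                         "kernel": kernel, "activation": activation,
                         "arch": arch, "error": msg})
        frame = pd.DataFrame(rows)
        if not frame.empty and "accuracy_mean" in frame:
            frame["best_arch"] = False
            for _, idx in frame.groupby(
                    ["domain", "window_s", "kernel", "activation"],
                    dropna=False).groups.items():
                sub = frame.loc[idx, "accuracy_mean"]
                if sub.notna().any():
                    frame.loc[sub.idxmax(), "best_arch"] = True
        return frame

    def mean_accuracy(self, domain: str) -> float:
        """Mean over all cells of one feature domain (grid ordering checks)."""
        accs = [rep.accuracy[0] for key, rep in self.cells.items()
                if key[0] == domain]
        if not accs:
            raise ValueError(f"no completed cells for domain {domain!r}")
        return float(np.mean(accs))


def _cell_seed(base_seed: int, key: tuple) -> int:
    # deterministic per-cell seed, independent of grid iteration order
    digest = zlib.crc32(repr(key).encode())
    return (base_seed * 31 + digest) % (2 ** 31)


def run_grid(recordings: Sequence[Recording],
             domains: Sequence[str] = ("time", "frequency"),
             windows: Sequence[float] = (0.25, 0.5, 1.0),
             kernels: Sequence[int] = (1, 3, 5),
             activations: Sequence[str] = ("relu",),
             archs: Sequence[str] = ("C64-128/D64",),
             cfg: TrainConfig = TrainConfig(),
             split_seed: int = 0,
             standardize: bool = True) -> GridResult:
    """Sweep the comparison grid on preprocessed (trimmed/notched) recordings.

    For each window length, recordings are segmented once and split 50/50
    per recording under ``split_seed``; all cells of that window length see
    the same window assignment.  Smoothing kernels apply to the frequency
    domain only (the time domain contributes one cell per window length).
    Per-cell training seeds are derived from the cell key, so results do not
    depend on grid iteration order; failures are recorded per cell and the
    grid continues.
    """
    if not (list(domains) and list(windows) and list(kernels)
            and list(activations) and list(archs)):
        raise ValueError("all condition lists must be non-empty")
    cells: dict[tuple, MetricsReport] = {}
    errors: dict[tuple, str] = {}
    for window in windows:
        spec = WindowSpec(win_len=window)
        wins: list[EpochWindow] = []
        for i, rec in enumerate(recordings):
            wins.extend(segment_windows(rec, spec, recording_index=i))
        train_w, test_w = split_train_test(
            wins, SplitSpec(train_fraction=0.5, seed=split_seed))
        for domain in domains:
            domain_kernels = [k for k in kernels] if domain == "frequency" else [None]
            for kernel in domain_kernels:
                feats = _extract(train_w, domain, kernel)
                feats_test = _extract(test_w, domain, kernel)
                if standardize:
                    feats = standardize_features(feats)
                    feats_test = standardize_features(feats_test)
                for activation in activations:
                    for arch_s in archs:
                        key = (domain, window, kernel, activation, arch_s)
                        try:
                            arch = parse_arch(arch_s,
                                              conv_activation=activation)
                            cell_cfg = replace(
                                cfg, seed=_cell_seed(cfg.seed, key))
                            result = train_kfold(feats, feats_test, arch,
                                                 cell_cfg)
                            cells[key] = evaluate_folds(result, feats_test)
                        except Exception as exc:  # keep sweeping
                            logger.warning("grid cell %s failed: %s", key, exc)
                            errors[key] = str(exc)
    return GridResult(cells=cells, errors=errors)


def _extract(wins: Sequence[EpochWindow], domain: str,
             kernel: int | None) -> list[FeatureMatrix]:
    if domain == "time":
        return [ccv_time(w) for w in wins]
    if domain == "frequency":
        k = SmoothingKernel(1 if kernel is None else kernel)
        return [ccv_frequency(w, k) for w in wins]
    raise ValueError(f"unknown feature domain: {domain!r}")
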