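"""End-to-end convenience wrappers: recordings → windows → features → metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cnn import TrainConfig, TrainResult, parse_arch, train_kfold
from .evaluation import MetricsReport, evaluate_folds
from .features import (FeatureMatrix, SmoothingKernel, ccv_frequency,
                       ccv_time, standardize_features)
from .io import Recording
from .preprocess import (EpochWindow, SplitSpec, WindowSpec, notch_powerline,
                         segment_windows, split_train_test, trim_transitions)

__all__ = ["prepare_windows", "extract_features", "run_pipeline",
           "PipelineResult"]


def prepare_windows(recordings: Sequence[Recording],
                    win_len: float = 0.25,
                    trim: float = 0.5,
                    base_freq: float | None = 60.0,
                    split_seed: int = 0,
                    stage: str = "imagined"
                    ) -> tuple[list[EpochWindow], list[EpochWindow]]:
    """Standard preprocessing: notch, trim, window, 50/50 per-recording split.

    ``base_freq=None`` skips the notch stage (synthetic data carries no mains
    artifact).  Only recordings of ``stage`` are processed.
    """
    windows: list[EpochWindow] = []
    spec = WindowSpec(win_len=win_len)
    for i, rec in enumerate(recordings):
        if rec.stage != stage:
            continue
        if base_freq is not None:
            rec = notch_powerline(rec, base_freq)
        rec = trim_transitions(rec, trim)
        windows.extend(segment_windows(rec, spec, recording_index=i))
    return split_train_test(windows, SplitSpec(train_fraction=0.5,
                                               seed=split_seed))


def extract_features(windows: Sequence[EpochWindow],
                     domain: str = "frequency",
                     kernel_width: int = 1,
                     standardize: bool = True) -> list[FeatureMatrix]:
    """Channel cross-covariance features of each window, optionally z-scored."""
    if domain == "time":
        feats = [ccv_time(w) for w in windows]
    elif domain == "frequency":
        k = SmoothingKernel(kernel_width)
        feats = [ccv_frequency(w, k) for w in windows]
    else:
        raise ValueError(f"unknown feature domain: {domain!r}")
    return standardize_features(feats) if standardize else feats


@dataclass
class PipelineResult:
    train_result: TrainResult
    report: MetricsReport
    n_train: int
    n_test: int


def run_pipeline(recordings: Sequence[Recording],
                 arch: str = "C64-128/D64",
                 activation: str = "relu",
                 domain: str = "frequency",
                 kernel_width: int = 1,
                 win_len: float = 0.25,
                 trim: float = 0.5,
                 base_freq: float | None = None,
                 cfg: TrainConfig = TrainConfig(),
                 split_seed: int = 0) -> PipelineResult:
    """Full decoding pipeline on a set of labelled recordings."""
    train_w, test_w = prepare_windows(recordings, win_len=win_len, trim=trim,
                                      base_freq=base_freq,
                                      split_seed=split_seed)
    feats_train = extract_features(train_w, domain, kernel_width)
    feats_test = extract_features(test_w, domain, kernel_width)
    spec = parse_arch(arch, conv_activation=activation)
    result = train_kfold(feats_train, feats_test, spec, cfg)
    report = evaluate_folds(result, feats_test)
    return PipelineResult(train_result=result, report=report,
                          n_train=len(feats_train), n_test=len(feats_test))
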