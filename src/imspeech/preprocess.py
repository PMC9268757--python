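"""Preprocessing: power-line notch filtering, transition trimming, windowing.

The pipeline mirrors a standard imagined-speech protocol: keep the imagined
stage of each trial, drop the first and last 0.5 s as transition states,
notch out the mains frequency and every harmonic below Nyquist, cut the
remainder into fixed non-overlapping windows, and split the windows of each
recording 50/50 into train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal

from .io import Recording

__all__ = [
    "WindowSpec",
    "EpochWindow",
    "SplitSpec",
    "notch_frequencies",
    "notch_powerline",
    "trim_transitions",
    "segment_windows",
    "split_train_test",
]


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping analysis window; ``win_len`` in seconds."""

    win_len: float

    def __post_init__(self) -> None:
        if self.win_len <= 0:
            raise ValueError("window length must be positive")

    def n_samples(self, fs: float) -> int:
        """Window length in samples; must be a positive integer for ``fs``."""
        w = self.win_len * fs
        w_int = round(w)
        if w_int < 1 or abs(w - w_int) > 1e-9 * max(1.0, w):
            raise ValueError(
                f"win_len × fs must be a positive integer, got {w}"
            )
        return w_int


@dataclass(frozen=True)
class EpochWindow:
    """One fixed-length window cut from a recording, with provenance."""

    data: np.ndarray  # channels × W
    fs: float
    label: str
    subject_id: str
    session_id: str
    recording_index: int
    window_index: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def origin(self) -> tuple[str, str, int, int]:
        return (self.subject_id, self.session_id,
                self.recording_index, self.window_index)


@dataclass(frozen=True)
class SplitSpec:
    """Per-recording random train/test split of windows."""

    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def notch_frequencies(fs: float, base_freq: float = 60.0) -> list[float]:
    """All multiples of ``base_freq`` strictly below the Nyquist frequency."""
    if fs <= 2 * base_freq:
        raise ValueError(
            f"fs={fs} Hz leaves no notch frequency below Nyquist for "
            f"base {base_freq} Hz"
        )
    nyquist = fs / 2.0
    freqs = []
    k = 1
    while k * base_freq < nyquist:
        freqs.append(k * base_freq)
        k += 1
    return freqs


def notch_powerline(rec: Recording, base_freq: float = 60.0,
                    quality: float = 30.0) -> Recording:
    """Remove the mains artifact at ``base_freq`` and all harmonics < Nyquist.

    A second-order IIR notch (quality factor ``quality``) is cascaded per
    harmonic and applied forward-backward (zero phase).  Linear and
    shape-preserving.
    """
    out = rec.data
    # generous reflect-padding keeps the filter's start-up transient out of
    # the retained samples
    padlen = min(rec.n_samples - 1, max(9, round(rec.fs)))
    for f0 in notch_frequencies(rec.fs, base_freq):
        b, a = scipy.signal.iirnotch(f0, quality, fs=rec.fs)
        out = scipy.signal.filtfilt(b, a, out, axis=-1, padlen=padlen)
    return rec.with_data(out)


def trim_transitions(rec: Recording, trim: float = 0.5) -> Recording:
    """Drop the first and last ``trim`` seconds (transition states).

    A 5 s imagined segment trimmed by 0.5 s yields the 4 s signal that the
    windowing stage consumes.
    """
    n_trim = round(trim * rec.fs)
    if rec.n_samples <= 2 * n_trim:
        raise ValueError(
            f"recording of {rec.duration:.3f} s too short to trim "
            f"{trim} s from both ends"
        )
    return rec.with_data(rec.data[:, n_trim:rec.n_samples - n_trim])


def segment_windows(rec: Recording, spec: WindowSpec,
                    recording_index: int = 0) -> list[EpochWindow]:
    """Cut a recording into consecutive non-overlapping windows.

    Windows start at sample 0; a trailing remainder shorter than the window
    is discarded (never zero-padded), so every window has exactly W samples.
    """
    w = spec.n_samples(rec.fs)
    n_win = rec.n_samples // w
    return [
        EpochWindow(
            data=rec.data[:, i * w:(i + 1) * w].copy(),
            fs=rec.fs,
            label=rec.prompt,
            subject_id=rec.subject_id,
            session_id=rec.session_id,
            recording_index=recording_index,
            window_index=i,
        )
        for i in range(n_win)
    ]


def split_train_test(windows: Sequence[EpochWindow],
                     split: SplitSpec = SplitSpec()) -> tuple[list[EpochWindow], list[EpochWindow]]:
    """Per-recording random split of windows into train and test.

    For each originating recording independently, a uniformly random
    ``train_fraction`` share of its windows goes to train and the rest to
    test (the extra window of an odd count goes to train).  The two sides
    partition the input and the draw is reproducible under ``split.seed``.

    Note this is a *window-level* protocol: windows of one trial can appear
    on both sides of the split, which leaks within-trial structure across
    the sets.  See :func:`split_by_recording` for the leakage-free variant.
    """
    by_rec: dict[tuple[str, str, int], list[EpochWindow]] = {}
    for w in windows:
        by_rec.setdefault(
            (w.subject_id, w.session_id, w.recording_index), []).append(w)
    rng = np.random.default_rng(split.seed)
    train: list[EpochWindow] = []
    test: list[EpochWindow] = []
    for key in sorted(by_rec):
        group = by_rec[key]
        n = len(group)
        if n < 2:
            raise ValueError(
                f"recording {key} contributes {n} window(s); need at least 2"
            )
        n_train = int(np.ceil(n * split.train_fraction))
        order = rng.permutation(n)
        chosen = set(order[:n_train].tolist())
        for i, w in enumerate(group):
            (train if i in chosen else test).append(w)
    return train, test


def split_by_recording(windows: Sequence[EpochWindow],
                       split: SplitSpec = SplitSpec()) -> tuple[list[EpochWindow], list[EpochWindow]]:
    """Recording-level split: every window of a trial lands on one side.

    Optional stricter protocol that removes the within-trial leakage of the
    window-level split; recordings are grouped per (subject, session, prompt)
    and split within each group so classes stay balanced.
    """
    by_rec: dict[tuple[str, str, int], list[EpochWindow]] = {}
    for w in windows:
        by_rec.setdefault(
            (w.subject_id, w.session_id, w.recording_index), []).append(w)
    by_class: dict[str, list[tuple[str, str, int]]] = {}
    for key, group in sorted(by_rec.items()):
        by_class.setdefault(group[0].label, []).append(key)
    rng = np.random.default_rng(split.seed)
    train: list[EpochWindow] = []
    test: list[EpochWindow] = []
    for label in sorted(by_class):
        keys = by_class[label]
        n_train = int(np.ceil(len(keys) * split.train_fraction))
        order = rng.permutation(len(keys))
        for rank, idx in enumerate(order):
            side = train if rank < n_train else test
            side.extend(by_rec[keys[idx]])
    return train, test
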