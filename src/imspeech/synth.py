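"""Synthetic multichannel EEG with class-dependent cross-spectral structure.

Each class is a latent linear model: a handful of band-limited Gaussian
sources, mixed into the channels by a class-specific mixing matrix, plus
white sensor noise.  Class identity therefore lives exactly where the
cross-covariance features look — in the inter-channel covariance of the
signals and of their spectra.  An optional per-channel circular delay jitter
emulates propagation delays of a source over the scalp: it scrambles
time-domain covariances while leaving magnitude spectra (and hence
frequency-domain features) untouched, which makes the time-vs-frequency
feature comparison a controlled, testable property of the generator.

This generator makes no attempt at biophysical realism: there is no head
model, no 1/f background, and no blink/EMG artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (PROMPTS, DatasetManifest, ManifestEntry, Recording,
                 write_recording)

__all__ = ["SynthSpec", "GroundTruth", "default_class_bands",
           "generate_class_model", "generate_trial", "generate_dataset",
           "save_dataset"]


def default_class_bands(n_classes: int, fs: float = 1000.0) -> list[list[tuple[float, float]]]:
    """Two disjoint passbands per class, staggered across classes.

    The usable range (2 Hz up to 90% of Nyquist) is divided into 2·n_classes
    equal slots; class c takes the central 80% of slots c and n_classes + c,
    giving every class a low and a higher frequency signature disjoint from
    its neighbours' at any sampling rate.
    """
    f_lo, f_hi = 2.0, 0.45 * fs
    n_slots = 2 * n_classes
    width = (f_hi - f_lo) / n_slots
    if width <= 0.2:
        raise ValueError(f"fs={fs} too low for {n_classes} default bands")

    def slot(i: int) -> tuple[float, float]:
        start = f_lo + i * width
        return (start + 0.1 * width, start + 0.9 * width)

    return [[slot(c), slot(n_classes + c)] for c in range(n_classes)]


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration; the defaults mirror one subject's inventory
    (11 prompts × 12 trials of 5 s at 62 channels)."""

    n_classes: int = 11
    n_channels: int = 62
    fs: float = 1000.0
    trial_duration: float = 5.0
    trials_per_class: int = 12
    n_sources: int = 4
    class_bands: tuple | None = None  # default: default_class_bands
    mixing_scale: float = 1.0
    noise_sigma: float = 1.0
    delay_jitter: bool = False
    max_delay: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= len(PROMPTS):
            raise ValueError(f"n_classes must be in 1..{len(PROMPTS)}")
        if self.n_sources < 1:
            raise ValueError("need at least one source")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        bands = self.class_bands
        if bands is None:
            bands = default_class_bands(self.n_classes, self.fs)
        if len(bands) != self.n_classes:
            raise ValueError("need one band list per class")
        for cls_bands in bands:
            for lo, hi in cls_bands:
                if not 0 < lo < hi < self.fs / 2:
                    raise ValueError(
                        f"band ({lo}, {hi}) outside (0, {self.fs / 2})")
        frozen = tuple(tuple((float(lo), float(hi)) for lo, hi in cb)
                       for cb in bands)
        object.__setattr__(self, "class_bands", frozen)

    @property
    def n_samples(self) -> int:
        n = round(self.trial_duration * self.fs)
        if n < 2:
            raise ValueError("trial too short")
        return n


@dataclass
class GroundTruth:
    """Latent class models and per-trial delays, kept for diagnostics."""

    mixing: list[np.ndarray]  # per class, n_channels × n_sources
    bands: list[list[tuple[float, float]]]
    delays: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)


def generate_class_model(spec: SynthSpec) -> GroundTruth:
    """Draw the per-class mixing matrices and assign band lists (seeded)."""
    rng = np.random.default_rng([spec.seed, 0x6d6978])
    mixing = [
        rng.normal(0.0, 1.0, size=(spec.n_channels, spec.n_sources))
        * spec.mixing_scale
        for _ in range(spec.n_classes)
    ]
    bands = [list(cb) for cb in spec.class_bands]
    return GroundTruth(mixing=mixing, bands=bands)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise ideally band-limited to ``band`` (zero-phase)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no DFT bin at n={n}, fs={fs}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    return x / std if std > 0 else x


def generate_trial(class_id: int, truth: GroundTruth, spec: SynthSpec,
                   trial_index: int = 0) -> Recording:
    """One labelled trial of the given class (stage "imagined").

    channels = mixing × sources + white noise; sources are unit-variance
    band-limited noise cycling through the class's bands.  With
    ``delay_jitter`` each channel is independently circularly shifted by a
    seeded random delay of at most ``max_delay`` samples, recorded in
    ``truth.delays``.
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id out of range: {class_id}")
    rng = np.random.default_rng([spec.seed, 0x7472, class_id, trial_index])
    n = spec.n_samples
    bands = truth.bands[class_id]
    sources = np.stack([
        _bandlimited_noise(rng, n, spec.fs, bands[s % len(bands)])
        for s in range(spec.n_sources)
    ])
    data = truth.mixing[class_id] @ sources
    if spec.noise_sigma > 0:
        data = data + spec.noise_sigma * rng.standard_normal(data.shape)
    if spec.delay_jitter:
        delays = rng.integers(0, spec.max_delay + 1, size=spec.n_channels)
        for ch, d in enumerate(delays):
            data[ch] = np.roll(data[ch], int(d))
        truth.delays[(class_id, trial_index)] = delays
    return Recording(
        subject_id="synth01",
        session_id="ses01",
        prompt=PROMPTS[class_id],
        stage="imagined",
        fs=spec.fs,
        data=data,
        channel_names=tuple(f"CH{i + 1:02d}" for i in range(spec.n_channels)),
        unit="a.u.",
    )


def generate_dataset(spec: SynthSpec = SynthSpec()
                     ) -> tuple[DatasetManifest, list[Recording], GroundTruth]:
    """Full balanced dataset: trials_per_class trials per class, labelled.

    A pure function of the spec — the same spec always yields the identical
    dataset.  The default spec produces 11 × 12 = 132 recordings, mirroring
    one subject's trial inventory.
    """
    truth = generate_class_model(spec)
    recordings: list[Recording] = []
    entries: list[ManifestEntry] = []
    for class_id in range(spec.n_classes):
        for t in range(spec.trials_per_class):
            rec = generate_trial(class_id, truth, spec, trial_index=t)
            recordings.append(rec)
            entries.append(ManifestEntry(
                path=f"trial_c{class_id:02d}_t{t:02d}.h5",
                subject_id=rec.subject_id,
                session_id=rec.session_id,
                prompt=rec.prompt,
                stage=rec.stage,
            ))
    manifest = DatasetManifest(entries=entries, fs=spec.fs,
                               channel_names=recordings[0].channel_names)
    return manifest, recordings, truth


def save_dataset(manifest: DatasetManifest, recordings: list[Recording],
                 truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write containers, manifest and a ground-truth sidecar to a directory."""
    import h5py

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for entry, rec in zip(manifest.entries, recordings):
        write_recording(rec, out_dir / entry.path)
    manifest.save(out_dir / "manifest.yaml")
    with h5py.File(out_dir / "ground_truth.h5", "w") as f:
        for c, m in enumerate(truth.mixing):
            f.create_dataset(f"mixing/class{c:02d}", data=m,
                             track_times=False)
            f.create_dataset(
                f"bands/class{c:02d}",
                data=np.asarray(truth.bands[c], dtype=np.float64),
                track_times=False)
        for (c, t), d in truth.delays.items():
            f.create_dataset(f"delays/class{c:02d}_trial{t:02d}", data=d,
                             track_times=False)
    return out_dir
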