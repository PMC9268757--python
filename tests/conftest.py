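"""Shared fixtures: random windows, small synthetic datasets, an EDF writer."""

from __future__ import annotations

import numpy as np
import pytest

from imspeech import PROMPTS, Recording, SynthSpec, generate_dataset
from imspeech.preprocess import EpochWindow


def make_window(rng: np.random.Generator, n_channels: int = 5,
                n_samples: int = 64, fs: float = 256.0,
                label: str = PROMPTS[0], window_index: int = 0) -> EpochWindow:
    return EpochWindow(
        data=rng.normal(size=(n_channels, n_samples)),
        fs=fs, label=label, subject_id="s01", session_id="ses01",
        recording_index=0, window_index=window_index,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def sample_recording(rng) -> Recording:
    return Recording(
        subject_id="s01", session_id="ses01", prompt="/iy/", stage="imagined",
        fs=1000.0, data=rng.normal(size=(4, 5000)),
        channel_names=("Fp1", "Fp2", "Cz", "Oz"),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """4-class, 8-channel, 2 s dataset — fast enough for pipeline tests."""
    spec = SynthSpec(
        n_classes=4, n_channels=8, fs=200.0, trial_duration=2.0,
        trials_per_class=4, n_sources=2, noise_sigma=0.3, seed=11,
        class_bands=[[(4.0, 10.0), (30.0, 40.0)],
                     [(10.0, 16.0), (40.0, 50.0)],
                     [(16.0, 22.0), (50.0, 60.0)],
                     [(22.0, 28.0), (60.0, 70.0)]],
    )
    return generate_dataset(spec)


def write_minimal_edf(path, data: np.ndarray, fs: float,
                      ch_names: list[str]) -> None:
    """Write a one-record EDF file (synthetic test fixture, int16 payload)."""
    n_ch, n_samp = data.shape
    record_dur = n_samp / fs
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    scaled = np.clip(
        (data - phys_min) / (phys_max - phys_min)
        * (dig_max - dig_min) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def f(value, width) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("synthetic patient", 80), f("synthetic recording", 80),
        f("01.01.20", 8), f("00.00.00", 8), f(256 * (1 + n_ch), 8),
        f("", 44), f(1, 8), f(f"{record_dur:g}", 8), f(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(f(name, 16) for name in ch_names),
        b"".join(f("", 80) for _ in ch_names),
        b"".join(f("uV", 8) for _ in ch_names),
        b"".join(f(f"{phys_min:g}", 8) for _ in ch_names),
        b"".join(f(f"{phys_max:g}", 8) for _ in ch_names),
        b"".join(f(dig_min, 8) for _ in ch_names),
        b"".join(f(dig_max, 8) for _ in ch_names),
        b"".join(f("", 80) for _ in ch_names),
        b"".join(f(n_samp, 8) for _ in ch_names),
        b"".join(f("", 32) for _ in ch_names),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig + scaled.tobytes())
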