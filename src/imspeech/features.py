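"""Channel cross-covariance features in the time and frequency domains.

For a window with C channels, the feature is the C × C matrix of zero-lag
covariances between channel signals:

    Cov(X_c1, X_c2) = E[(X_c1 − E[X_c1])(X_c2 − E[X_c2])],
    E[X_ch] = (1/W) Σ_i x_i,

computed either over the raw samples (time domain) or over the one-sided
magnitude spectra of the channels (frequency domain), optionally smoothed by
a short moving average (B0 = none, B3 = 3 bins, B5 = 5 bins).  Covariance on
magnitude spectra discards the Fourier phase, so per-channel propagation
delays — circular time shifts — leave the frequency-domain feature matrix
unchanged while generically changing the time-domain one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage

from .preprocess import EpochWindow

__all__ = [
    "Spectrum",
    "SmoothingKernel",
    "FeatureMatrix",
    "expected_value",
    "cross_covariance",
    "ccv_time",
    "channel_spectrum",
    "smooth_spectrum",
    "ccv_frequency",
    "standardize_features",
]


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectra (channels × bins) of a window.

    ``mag[c, k] = |Σ_t x_c(t) exp(−j2πkt/n)|`` for bins k = 0 … floor(n/2);
    unnormalized DFT convention, so the two-sided squared magnitudes sum to
    n × Σ x² (Parseval).
    """

    mag: np.ndarray
    n: int
    fs: float

    def __post_init__(self) -> None:
        mag = np.asarray(self.mag, dtype=np.float64)
        if mag.ndim != 2:
            raise ValueError("mag must be channels × bins")
        if mag.shape[1] != self.n // 2 + 1:
            raise ValueError(
                f"one-sided spectrum of n={self.n} needs {self.n // 2 + 1} "
                f"bins, got {mag.shape[1]}"
            )
        if np.any(mag < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "mag", mag)

    @property
    def n_bins(self) -> int:
        return self.mag.shape[1]

    @property
    def bin_resolution(self) -> float:
        """Frequency spacing of adjacent bins, fs/n in Hz."""
        return self.fs / self.n


@dataclass(frozen=True)
class SmoothingKernel:
    """Moving-average width in bins; 1 ≡ B0 (identity), 3 ≡ B3, 5 ≡ B5."""

    width: int = 1

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("kernel width must be odd and positive")

    @property
    def name(self) -> str:
        return f"B{0 if self.width == 1 else self.width}"


@dataclass(frozen=True)
class FeatureMatrix:
    """C × C cross-covariance feature matrix of one window."""

    values: np.ndarray
    domain: str  # "time" or "frequency"
    label: str
    origin: tuple
    kernel: SmoothingKernel | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("feature matrix must be square")
        if self.domain not in ("time", "frequency"):
            raise ValueError(f"unknown domain: {self.domain!r}")
        object.__setattr__(self, "values", values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def expected_value(x: np.ndarray) -> float:
    """Sample mean (1/W) Σ x_i of a window's channel signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty vector")
    return float(x.mean())


def cross_covariance(x1: np.ndarray, x2: np.ndarray) -> float:
    """Zero-lag cross-covariance with population (1/W) normalization."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError("vectors must have equal length")
    if x1.size < 2:
        raise ValueError("need at least 2 samples")
    return float(((x1 - x1.mean()) * (x2 - x2.mean())).mean())


def _cov_matrix(rows: np.ndarray) -> np.ndarray:
    """All pairwise zero-lag covariances of the rows (1/W normalization)."""
    centered = rows - rows.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / rows.shape[1]
    # symmetrize away the last-bit asymmetry of floating-point matmul
    return (cov + cov.T) / 2.0


def ccv_time(win: EpochWindow) -> FeatureMatrix:
    """Time-domain channel cross-covariance matrix of a window.

    Entry (i, j) is the zero-lag covariance between channels i and j over the
    window's raw samples; the result is symmetric positive semidefinite.
    """
    if win.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if win.n_samples < 2:
        raise ValueError("need at least 2 samples")
    return FeatureMatrix(values=_cov_matrix(win.data), domain="time",
                         label=win.label, origin=win.origin)


def channel_spectrum(win: EpochWindow) -> Spectrum:
    """Per-channel one-sided magnitude spectrum of a window (n = W)."""
    if win.n_samples < 2:
        raise ValueError("need at least 2 samples")
    mag = np.abs(np.fft.rfft(win.data, axis=1))
    return Spectrum(mag=mag, n=win.n_samples, fs=win.fs)


def smooth_spectrum(spec: Spectrum, kernel: SmoothingKernel) -> Spectrum:
    """Centered moving average over the magnitude bins of each channel.

    Width 1 (B0) is the identity.  Edge bins are handled by replicating the
    boundary bin, which keeps constant spectra exactly constant and preserves
    non-negativity.
    """
    if kernel.width > spec.n_bins:
        raise ValueError(
            f"kernel width {kernel.width} exceeds {spec.n_bins} spectrum bins"
        )
    if kernel.width == 1:
        return spec
    mag = scipy.ndimage.uniform_filter1d(
        spec.mag, size=kernel.width, axis=1, mode="nearest")
    return Spectrum(mag=np.maximum(mag, 0.0), n=spec.n, fs=spec.fs)


def ccv_frequency(win: EpochWindow,
                  kernel: SmoothingKernel = SmoothingKernel(1)) -> FeatureMatrix:
    """Frequency-domain channel cross-covariance matrix of a window.

    Covariance is taken across frequency bins of the (optionally smoothed)
    magnitude spectra.  Because magnitudes discard phase, the result is
    invariant to per-channel circular time shifts of the window.
    """
    if win.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if win.n_samples < 4:
        raise ValueError("need at least 4 samples")
    spec = smooth_spectrum(channel_spectrum(win), kernel)
    return FeatureMatrix(values=_cov_matrix(spec.mag), domain="frequency",
                         label=win.label, origin=win.origin, kernel=kernel)


def save_features(mats: Sequence[FeatureMatrix], path,
                  win_len: float | None = None,
                  split: Sequence[str] | None = None):
    """Serialize a feature set to the internal HDF5 container.

    Stores the stacked matrices with per-matrix labels, domain tags, kernel
    widths and origins, plus optional window length and train/test split
    assignment.  Loadable with :func:`load_features`.
    """
    import h5py

    if not mats:
        raise ValueError("empty feature list")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.stack([m.values for m in mats]),
                         track_times=False)
        str_t = h5py.string_dtype()
        f.create_dataset("labels", data=[m.label for m in mats], dtype=str_t,
                         track_times=False)
        f.create_dataset("domains", data=[m.domain for m in mats],
                         dtype=str_t, track_times=False)
        f.create_dataset(
            "kernel_widths",
            data=[0 if m.kernel is None else m.kernel.width for m in mats],
            track_times=False)
        f.create_dataset("origins",
                         data=[[str(x) for x in m.origin] for m in mats],
                         dtype=str_t, track_times=False)
        if win_len is not None:
            f.attrs["win_len"] = float(win_len)
        if split is not None:
            f.create_dataset("split", data=list(split), dtype=str_t,
                             track_times=False)
    return path


def load_features(path) -> list[FeatureMatrix]:
    """Inverse of :func:`save_features` (origins come back as string tuples)."""
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][()]
        labels = [s.decode() for s in f["labels"][()]]
        domains = [s.decode() for s in f["domains"][()]]
        widths = f["kernel_widths"][()]
        origins = [tuple(x.decode() for x in row) for row in f["origins"][()]]
    return [
        FeatureMatrix(
            values=values[i], domain=domains[i], label=labels[i],
            origin=origins[i],
            kernel=None if widths[i] == 0 else SmoothingKernel(int(widths[i])),
        )
        for i in range(len(labels))
    ]


def standardize_features(mats: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
    """Z-score each feature matrix independently over its entries.

    Raw covariances span orders of magnitude across windows; per-matrix
    standardization puts every input on the scale the network's tanh/relu
    units expect.  A matrix with zero spread maps to the all-zero matrix.
    """
    if not mats:
        raise ValueError("empty feature list")
    out = []
    for m in mats:
        v = m.values
        std = v.std()
        z = np.zeros_like(v) if std == 0 else (v - v.mean()) / std
        out.append(FeatureMatrix(values=z, domain=m.domain, label=m.label,
                                 origin=m.origin, kernel=m.kernel))
    return out
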