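"""Data model and I/O for labelled multichannel EEG trials.

A trial ("recording") is a channels × samples float matrix with a sampling
rate, a prompt label (one of 7 phonemes and 4 words), and the experiment
stage it was cut from.  Recordings are stored one-per-file in an HDF5
container alongside a YAML manifest; EDF files are read through :mod:`mne`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import yaml

__all__ = [
    "PROMPTS",
    "STAGES",
    "Recording",
    "ManifestEntry",
    "DatasetManifest",
    "check_prompt",
    "encode_prompt",
    "decode_prompt",
    "read_recording",
    "write_recording",
    "class_priors",
    "truncate_prior",
]

#: The 11 admissible prompt labels: 7 phonemes then 4 words.  Their position
#: in this tuple is the stable integer encoding used for one-hot targets and
#: confusion-matrix axes.
PROMPTS: tuple[str, ...] = (
    "/iy/", "/uw/", "/piy/", "/tiy/", "/diy/", "/m/", "/n/",
    "gnaw", "knew", "pat", "pot",
)

_PROMPT_INDEX: dict[str, int] = {p: i for i, p in enumerate(PROMPTS)}

#: Protocol stages of a trial; only "imagined" is decoded by default.
STAGES: tuple[str, ...] = ("rest", "stimulus", "imagined", "spoken")


def check_prompt(label: str) -> str:
    """Validate a prompt label, returning it unchanged.

    Raises ``ValueError`` for anything outside the 11 admissible prompts.
    """
    if label not in _PROMPT_INDEX:
        raise ValueError(f"unknown prompt label: {label!r} (expected one of {PROMPTS})")
    return label


def encode_prompt(label: str) -> int:
    """Integer class index (0–10) of a prompt label."""
    check_prompt(label)
    return _PROMPT_INDEX[label]


def decode_prompt(index: int) -> str:
    """Inverse of :func:`encode_prompt`."""
    if not 0 <= index < len(PROMPTS):
        raise ValueError(f"prompt index out of range: {index}")
    return PROMPTS[index]


@dataclass(frozen=True)
class Recording:
    """One labelled EEG trial: ``data`` is channels × samples, in ``unit``."""

    subject_id: str
    session_id: str
    prompt: str
    stage: str
    fs: float
    data: np.ndarray
    channel_names: tuple[str, ...]
    unit: str = "V"

    def __post_init__(self) -> None:
        check_prompt(self.prompt)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage: {self.stage!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2 or data.shape[1] < 1:
            raise ValueError("data must be a 2-D channels × samples matrix")
        if data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {data.shape[0]} rows but {len(self.channel_names)} "
                "channel names"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with ``data`` replaced (metadata kept)."""
        return replace(self, data=data)


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    session_id: str
    prompt: str
    stage: str

    def __post_init__(self) -> None:
        check_prompt(self.prompt)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage: {self.stage!r}")


@dataclass
class DatasetManifest:
    """Inventory of a dataset: one entry per recording file, shared fs/channels."""

    entries: list[ManifestEntry]
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "fs": float(self.fs),
            "channel_names": list(self.channel_names),
            "entries": [
                {
                    "path": e.path,
                    "subject_id": e.subject_id,
                    "session_id": e.session_id,
                    "prompt": e.prompt,
                    "stage": e.stage,
                }
                for e in self.entries
            ],
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        doc = yaml.safe_load(Path(path).read_text())
        entries = [ManifestEntry(**e) for e in doc["entries"]]
        return cls(entries=entries, fs=float(doc["fs"]),
                   channel_names=tuple(doc["channel_names"]))


# ---------------------------------------------------------------------------
# container I/O

def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to the internal HDF5 container (lossless float64).

    The payload is written with HDF5 object timestamps disabled, so two
    writes of the same recording produce byte-identical files.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=rec.data, track_times=False)
        dset.attrs["unit"] = rec.unit
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["session_id"] = rec.session_id
        f.attrs["prompt"] = rec.prompt
        f.attrs["stage"] = rec.stage
        f.attrs["fs"] = float(rec.fs)
        f.attrs["channel_names"] = [str(c) for c in rec.channel_names]
    return path


def _read_container(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
            prompt=str(f.attrs["prompt"]),
            stage=str(f.attrs["stage"]),
            fs=float(f.attrs["fs"]),
            data=f["data"][()],
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            unit=str(f["data"].attrs.get("unit", "V")),
        )


def _read_edf(path: Path, entry: ManifestEntry) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts, channels × samples, header channel order
    return Recording(
        subject_id=entry.subject_id,
        session_id=entry.session_id,
        prompt=entry.prompt,
        stage=entry.stage,
        fs=float(raw.info["sfreq"]),
        data=data,
        channel_names=tuple(raw.ch_names),
        unit="V",
    )


def read_recording(path: str | Path,
                   manifest_entry: ManifestEntry | None = None,
                   expected_channels: int | None = None) -> Recording:
    """Read one recording from EDF or the internal HDF5 container.

    EDF files carry no prompt/stage metadata, so a ``manifest_entry`` is
    required for them; the container is self-describing.  If
    ``expected_channels`` is given, a mismatch with the file header is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        if manifest_entry is None:
            raise ValueError("EDF input requires a manifest entry for labels")
        rec = _read_edf(path, manifest_entry)
    else:
        rec = _read_container(path)
        if manifest_entry is not None:
            check_prompt(manifest_entry.prompt)
    if expected_channels is not None and rec.n_channels != expected_channels:
        raise ValueError(
            f"channel count mismatch: file has {rec.n_channels}, "
            f"manifest says {expected_channels}"
        )
    return rec


# ---------------------------------------------------------------------------
# label bookkeeping

def class_priors(labels: Sequence[str]) -> dict[str, float]:
    """Empirical class priors (count / total) of a label multiset.

    The returned probabilities are exact (they sum to 1 up to rounding error);
    use :func:`truncate_prior` to reproduce 3-decimal reporting.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    for lab in labels:
        check_prompt(lab)
    total = len(labels)
    priors: dict[str, float] = {}
    for lab in labels:
        priors[lab] = priors.get(lab, 0.0) + 1.0
    return {lab: count / total for lab, count in priors.items()}


def truncate_prior(p: float, decimals: int = 3) -> float:
    """Truncate (not round) a probability to ``decimals`` places for reporting.

    83/993 reports as 0.083 and 95/993 as 0.095 under truncation.
    """
    scale = 10 ** decimals
    return math.floor(p * scale) / scale
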