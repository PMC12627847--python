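"""Multichannel recording container and file I/O.

A :class:`Recording` is the substrate of every signal-processing stage:
a channels × time matrix with a sampling rate, channel labels, a montage
tag, a behavioural-state tag, a per-sample artifact mask and a provenance
log of the operations applied so far.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_recording", "write_recording_txt"]


@dataclass
class Recording:
    """Multichannel time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in arbitrary (typically µV) units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``samples``.
    montage : str
        ``"monopolar"`` or ``"bipolar"``.
    state_tag : str
        ``"eyes_open"``, ``"eyes_closed"`` or ``"wireless"``.
    artifact_mask : ndarray of bool, shape (n_times,)
        True where samples are artifactual and must be excluded from
        epoching downstream.
    log : list of str
        Provenance of applied operations.
    meta : dict
        Free-form metadata (e.g. generating model coefficients).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list
    montage: str = "monopolar"
    state_tag: str = "eyes_closed"
    artifact_mask: np.ndarray = None
    log: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.shape[1], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.samples.shape[1],):
                raise ValueError("artifact_mask length must equal n_times")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_times / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; have {self.channel_labels}"
            ) from None
        return self.samples[idx]

    def copy_with(self, **kw) -> "Recording":
        """Shallow-copying ``dataclasses.replace`` that deep-copies arrays."""
        kw.setdefault("samples", self.samples.copy())
        kw.setdefault("artifact_mask", self.artifact_mask.copy())
        kw.setdefault("log", list(self.log))
        kw.setdefault("meta", dict(self.meta))
        return replace(self, **kw)


def write_recording_txt(rec: Recording, path, fmt: str = "%.8g") -> None:
    """Write a recording as whitespace-delimited text plus a JSON sidecar.

    The text file holds one column per channel; the sidecar ``<path>.json``
    records fs, labels, montage and state tag so the recording round-trips.
    """
    path = Path(path)
    np.savetxt(path, rec.samples.T, fmt=fmt)
    sidecar = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "montage": rec.montage,
        "state_tag": rec.state_tag,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_recording(path, fs: float = None, channel_labels=None) -> Recording:
    """Read a recording from EDF, BrainVision or delimited text.

    EDF (``.edf``) and BrainVision (``.vhdr``) files are read through MNE.
    Text files expect one column per channel and look for a JSON sidecar
    ``<path>.json`` with ``fs`` and ``channel_labels``; either can instead be
    passed explicitly.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".vhdr"):
        import mne

        if suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        return Recording(
            samples=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            log=[f"read {path.name}"],
        )

    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        fs = fs if fs is not None else side["fs"]
        channel_labels = channel_labels or side.get("channel_labels")
    if fs is None:
        raise ValueError(f"no sampling rate for {path}: pass fs or provide a sidecar")
    data = np.loadtxt(path, ndmin=2).T
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(
        samples=data, fs=float(fs), channel_labels=list(channel_labels),
        log=[f"read {path.name}"],
    )
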