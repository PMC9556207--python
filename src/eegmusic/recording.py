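"""Multichannel EEG recording container.

The recording is a plain ``(n_channels, n_samples)`` float matrix in microvolts
plus a sampling rate — the minimal in-memory representation every stage of the
pipeline (simulation, denoising, windowed classification) operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording", "DEFAULT_MONTAGE"]

#: Frontal three-electrode montage used by the study protocol.
DEFAULT_MONTAGE = ("FP1", "FP2", "FPZ")


@dataclass
class EEGRecording:
    """A multichannel EEG time series in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, amplitudes in µV.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        One label per channel (defaults to ``ch0, ch1, ...``).
    start_time
        Offset of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = field(default=())
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording needs at least one channel and one sample")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.n_channels))
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, including ``start_time``."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Same metadata, new sample matrix (shape must match)."""
        if np.shape(data) != self.data.shape:
            raise ValueError("replacement data must keep the recording shape")
        return EEGRecording(
            data=np.array(data, dtype=float),
            fs=self.fs,
            channel_labels=self.channel_labels,
            start_time=self.start_time,
        )

    def windows(self, window_s: float = 0.5) -> np.ndarray:
        """Split into non-overlapping windows of ``window_s`` seconds.

        Returns an array of shape ``(n_windows, n_channels, samples_per_window)``;
        a trailing partial window is dropped.
        """
        step = int(round(window_s * self.fs))
        if step < 1:
            raise ValueError("window shorter than one sample")
        n_win = self.n_samples // step
        return self.data[:, : n_win * step].reshape(self.n_channels, n_win, step).transpose(1, 0, 2)
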