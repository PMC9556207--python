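"""Plain-text readers and writers for recordings, labels, cohorts and music.

The canonical EEG container is a wide CSV: a comment line carrying the
sampling metadata, then a header row of channel labels, then one row per
sample in µV. Values are written at full double precision so a write/read
round trip is exact.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .feedback import MusicSegment
from .recording import EEGRecording
from .synth import ScaleCohort

__all__ = [
    "EEGParseError",
    "write_eeg",
    "read_eeg",
    "write_labels",
    "read_labels",
    "write_cohort",
    "read_cohort",
    "write_music_events",
]


class EEGParseError(ValueError):
    """Raised when an EEG file cannot be parsed; names the offending line."""


def write_eeg(rec: EEGRecording, path) -> None:
    """Write a recording as wide CSV (one column per channel, µV)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# eegmusic fs_hz={rec.fs!r} start_time_s={rec.start_time!r}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")


def read_eeg(path) -> EEGRecording:
    """Read a wide-CSV recording written by :func:`write_eeg`.

    Raises :class:`EEGParseError` naming the line for empty files, missing
    metadata, or missing/garbled samples.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise EEGParseError(f"{path}: cannot read file ({exc})") from exc
    if not text.strip():
        raise EEGParseError(f"{path}: file is empty")
    lines = text.splitlines()
    meta_line = lines[0]
    if not meta_line.startswith("#"):
        raise EEGParseError(f"{path}, line 1: expected a '# eegmusic fs_hz=...' metadata line")
    meta = dict(
        tok.split("=", 1) for tok in meta_line.lstrip("# ").split() if "=" in tok
    )
    try:
        fs = float(meta["fs_hz"])
        start = float(meta.get("start_time_s", 0.0))
    except (KeyError, ValueError) as exc:
        raise EEGParseError(f"{path}, line 1: bad metadata ({exc})") from exc
    if len(lines) < 3:
        raise EEGParseError(f"{path}: no samples found")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines[1:])))
    except Exception as exc:
        raise EEGParseError(f"{path}: malformed CSV ({exc})") from exc
    if df.isna().any().any():
        bad_row = int(df.isna().any(axis=1).idxmax())
        raise EEGParseError(f"{path}, line {bad_row + 3}: missing sample value")
    data = df.to_numpy(dtype=float).T
    return EEGRecording(data=data, fs=fs, channel_labels=tuple(df.columns), start_time=start)


def write_labels(labels, path) -> None:
    """State labels as CSV ``window_index,state``."""
    pd.DataFrame({"window_index": range(len(labels)), "state": list(labels)}).to_csv(path, index=False)


def read_labels(path) -> tuple[str, ...]:
    df = pd.read_csv(path)
    return tuple(df.sort_values("window_index")["state"])


def write_cohort(cohort: ScaleCohort, path) -> None:
    cohort.scores.to_csv(path, index=False)


def read_cohort(path) -> ScaleCohort:
    return ScaleCohort(pd.read_csv(path))


def write_music_events(segments: list[MusicSegment], path) -> None:
    """Music segments as a CSV event table (one row per note event)."""
    rows = []
    for seg in segments:
        for onset, pitch, dur, vel in seg.events:
            rows.append(
                {
                    "segment_index": seg.segment_index,
                    "valence": seg.valence,
                    "onset_s": onset,
                    "pitch": pitch,
                    "duration_s": dur,
                    "velocity": vel,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
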