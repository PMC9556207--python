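"""Emotion-state sequences, 6-s music-segment decisions, and the session protocol.

The closed loop decodes one of three emotion states (``active`` / ``passive``
/ ``normal``) for every non-overlapping 0.5-s EEG window, aggregates each
block of twelve windows (6 s) into a music-stimulus decision by majority
vote, and renders one of three fixed symbolic motifs (positive / medium /
negative valence) as the feedback stimulus. A 45-minute cap on the session
protocol is enforced.

The classifiers of :mod:`eegmusic.cnn` and :mod:`eegmusic.boosting` are
binary (positive/active vs negative/passive); the ternary state is obtained
by dual-thresholding the positive-class probability: scores above the upper
threshold are ``active``, below the lower threshold ``passive``, in between
``normal``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import boosting, cnn
from .recording import EEGRecording
from .synth import STATES, WINDOW_S

__all__ = [
    "EmotionSequence",
    "MusicSegment",
    "ProtocolSchedule",
    "VALENCES",
    "STATE_TO_VALENCE",
    "classify_windows",
    "window_scores",
    "scores_to_states",
    "segment_decision",
    "marker_count",
    "render_music",
    "render_session",
    "fragment_trend",
    "schedule_protocol",
    "DEFAULT_STAGES",
]

VALENCES = ("positive", "medium", "negative")

#: Default state -> music mapping: reinforce the decoded state's direction
#: (an activated state receives positive, exciting music). Configurable for
#: compensatory mappings.
STATE_TO_VALENCE = {"active": "positive", "normal": "medium", "passive": "negative"}

SEGMENT_S = 6.0
WINDOWS_PER_SEGMENT = int(SEGMENT_S / WINDOW_S)  # 12


@dataclass
class EmotionSequence:
    """Ordered 0.5-s emotion-state labels decoded from one recording."""

    labels: tuple[str, ...]
    source: str = "truth"  # cnn | gb | ensemble | truth
    window_s: float = WINDOW_S

    def __post_init__(self) -> None:
        if self.window_s != WINDOW_S:
            raise ValueError(f"window_s must be exactly {WINDOW_S}")
        if not self.labels:
            raise ValueError("label sequence is empty")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")
        self.labels = tuple(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MusicSegment:
    """One 6-s music stimulus: a valence plus symbolic note events.

    Events are ``(onset_s, midi_pitch, duration_s, velocity)`` tuples whose
    onsets lie in ``[0, 6)`` and which never sound past the 6-s boundary.
    """

    valence: str
    events: list[tuple[float, int, float, int]]
    segment_index: int = 0
    duration_s: float = SEGMENT_S

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence {self.valence!r}")
        if self.duration_s != SEGMENT_S:
            raise ValueError(f"segments last exactly {SEGMENT_S} s")
        for onset, _, dur, _ in self.events:
            if not (0.0 <= onset < SEGMENT_S) or onset + dur > SEGMENT_S + 1e-9:
                raise ValueError("event outside the 6-s segment")

    @property
    def mean_pitch(self) -> float:
        return float(np.mean([e[1] for e in self.events]))


def _calibrated(p: np.ndarray, scale: float) -> np.ndarray:
    """Temperature scaling on the logit scale: logistic(scale * logit(p))."""
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return 1.0 / (1.0 + np.exp(-scale * np.log(p / (1.0 - p))))


def window_scores(
    rec: EEGRecording,
    cnn_model: cnn.CNNModel | None = None,
    gb_model: boosting.GBModel | None = None,
    gb_decim: int = 5,
    gb_featurizer=None,
    calibration: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, str]:
    """Positive-class score per 0.5-s window, averaged over supplied models.

    ``calibration`` optionally maps model names (``"cnn"`` / ``"gb"``) to
    temperature factors applied to each model's probability on the logit
    scale before averaging; classifiers trained to saturation need
    temperatures well below 1 for the mid-range (``normal``) band of the
    dual-threshold rule to be populated.
    """
    if rec.duration_s < WINDOW_S:
        raise ValueError("recording shorter than one 0.5-s window")
    windows = rec.windows(WINDOW_S)
    calibration = calibration or {}

    scores = []
    sources = []
    if cnn_model is not None:
        if not cnn_model.trained:
            raise ValueError("CNN model is untrained")
        p = cnn.predict_proba(cnn_model, windows)[:, 1]
        scores.append(_calibrated(p, calibration.get("cnn", 1.0)))
        sources.append("cnn")
    if gb_model is not None:
        if not gb_model.trained:
            raise ValueError("GB model is untrained")
        if gb_featurizer is None:
            feats = boosting.time_indexed_features(windows, decim=gb_decim)
        else:
            feats = gb_featurizer(windows)
        p = gb_model.predict_proba(feats)
        scores.append(_calibrated(p, calibration.get("gb", 1.0)))
        sources.append("gb")
    if not scores:
        raise ValueError("at least one trained classifier is required")
    return np.mean(scores, axis=0), "+".join(sources)


def scores_to_states(s: np.ndarray, thresholds: tuple[float, float] = (0.4, 0.6)) -> np.ndarray:
    """Dual-threshold ternary rule on positive-class scores."""
    theta_lo, theta_hi = thresholds
    if not theta_lo < theta_hi:
        raise ValueError("thresholds must satisfy theta_lo < theta_hi")
    return np.where(s > theta_hi, "active", np.where(s < theta_lo, "passive", "normal"))


def classify_windows(
    rec: EEGRecording,
    cnn_model: cnn.CNNModel | None = None,
    gb_model: boosting.GBModel | None = None,
    thresholds: tuple[float, float] = (0.4, 0.6),
    gb_decim: int = 5,
    gb_featurizer=None,
    calibration: Mapping[str, float] | None = None,
) -> EmotionSequence:
    """Decode one emotion state per 0.5-s window.

    The window's valence score is the (optionally temperature-calibrated)
    positive-class probability averaged over whichever trained classifiers
    are supplied (at least one); dual thresholds ``(theta_lo, theta_hi)``
    map the score to the ternary state.
    """
    s, source = window_scores(
        rec, cnn_model, gb_model, gb_decim=gb_decim,
        gb_featurizer=gb_featurizer, calibration=calibration,
    )
    labels = scores_to_states(s, thresholds)
    return EmotionSequence(labels=tuple(labels), source=source)


def segment_decision(
    seq: EmotionSequence,
    mapping: Mapping[str, str] = STATE_TO_VALENCE,
) -> list[str]:
    """Majority vote over each block of twelve 0.5-s windows -> one valence.

    Ties go to ``medium`` (the neutral stimulus); a trailing partial block is
    dropped.
    """
    if len(seq) < WINDOWS_PER_SEGMENT:
        raise ValueError("need at least 12 windows (one 6-s block)")
    decisions = []
    n_blocks = len(seq) // WINDOWS_PER_SEGMENT
    for b in range(n_blocks):
        block = seq.labels[b * WINDOWS_PER_SEGMENT : (b + 1) * WINDOWS_PER_SEGMENT]
        counts = Counter(block)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            decisions.append("medium")
        else:
            decisions.append(mapping[top[0][0]])
    return decisions


def marker_count(n_segments: int, segment_s: float = SEGMENT_S, window_s: float = WINDOW_S) -> int:
    """Number of 0.5-s state markers behind ``n_segments`` music decisions.

    399 six-second segments correspond to 4788 markers.
    """
    if n_segments < 0:
        raise ValueError("n_segments must be non-negative")
    ratio = segment_s / window_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("segment_s must be an integer multiple of window_s")
    return int(n_segments * round(ratio))


# ---------------------------------------------------------------------------
# Symbolic music rendering
# ---------------------------------------------------------------------------

# Motif tables: (scale degrees as MIDI pitches, beats-per-minute, velocity).
# Positive: ascending C-major, bright and fast; negative: descending A-minor,
# slow and soft; medium: a calm C-pentatonic drone.
_MOTIFS = {
    "positive": {"pitches": [60, 62, 64, 65, 67, 69, 71, 72], "bpm": 120, "velocity": 96},
    "medium": {"pitches": [60, 62, 65, 67, 69], "bpm": 90, "velocity": 72},
    "negative": {"pitches": [57, 55, 53, 52, 50, 48], "bpm": 60, "velocity": 56},
}


def render_music(valence: str, seed: int = 0, segment_index: int = 0) -> MusicSegment:
    """Render one 6-s symbolic music segment for a valence.

    Note onsets tile the segment at the motif's beat length; pitches walk the
    motif table (ascending for positive, descending for negative) with a
    seeded occasional octave ornament. Deterministic under ``(valence, seed)``.
    """
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}; expected one of {VALENCES}")
    motif = _MOTIFS[valence]
    rng = np.random.default_rng(seed)
    beat_s = 60.0 / motif["bpm"]
    n_notes = int(SEGMENT_S / beat_s)
    events = []
    for k in range(n_notes):
        onset = k * beat_s
        pitch = motif["pitches"][k % len(motif["pitches"])]
        if rng.random() < 0.15:  # sparse ornament, one octave toward the valence
            pitch += 12 if valence == "positive" else (-12 if valence == "negative" else 0)
        dur = min(beat_s * 0.9, SEGMENT_S - onset)
        events.append((round(onset, 6), int(pitch), round(dur, 6), motif["velocity"]))
    return MusicSegment(valence=valence, events=events, segment_index=segment_index)


def render_session(valences: Sequence[str], seed: int = 0) -> list[MusicSegment]:
    """Render the music for a whole session's segment decisions."""
    rng = np.random.default_rng(seed)
    return [
        render_music(v, seed=int(rng.integers(2**31)), segment_index=i)
        for i, v in enumerate(valences)
    ]


def fragment_trend(sessions: Sequence[Sequence[MusicSegment | str]]) -> pd.DataFrame:
    """Count music valences per trial and fit a linear trend per valence.

    Returns a frame indexed by trial with one count column per valence plus a
    ``slope`` row-independent attribute table accessible via
    ``df.attrs['slopes']`` (least-squares slope of counts over trials; its
    sign is the monotone-trend flag).
    """
    if not sessions:
        raise ValueError("need at least one trial")
    rows = []
    for i, segs in enumerate(sessions):
        vals = [s.valence if isinstance(s, MusicSegment) else s for s in segs]
        counts = Counter(vals)
        rows.append({"trial": i + 1, **{v: counts.get(v, 0) for v in VALENCES}})
    df = pd.DataFrame(rows).set_index("trial")
    slopes = {}
    x = np.arange(1, len(sessions) + 1, dtype=float)
    for v in VALENCES:
        slopes[v] = float(np.polyfit(x, df[v].to_numpy(dtype=float), 1)[0]) if len(x) > 1 else 0.0
    df.attrs["slopes"] = slopes
    return df


# ---------------------------------------------------------------------------
# Session protocol
# ---------------------------------------------------------------------------

#: Default stages of one feedback session (minutes): scale rating 10,
#: preparation 3, breathing practice 3, two 13-minute feedback exercises.
DEFAULT_STAGES = (
    ("scales", 10.0),
    ("preparation", 3.0),
    ("breathing", 3.0),
    ("feedback_1", 13.0),
    ("feedback_2", 13.0),
)

MAX_SESSION_MIN = 45.0


@dataclass
class ProtocolSchedule:
    """Ordered session stages; total duration capped at 45 minutes."""

    stages: tuple[tuple[str, float], ...] = field(default=DEFAULT_STAGES)

    def __post_init__(self) -> None:
        self.stages = tuple((str(n), float(d)) for n, d in self.stages)
        if any(d <= 0 for _, d in self.stages):
            raise ValueError("stage durations must be positive")
        if self.total_min > MAX_SESSION_MIN:
            raise ValueError(
                f"schedule totals {self.total_min:g} min, exceeding the {MAX_SESSION_MIN:g}-min cap"
            )

    @property
    def total_min(self) -> float:
        return float(sum(d for _, d in self.stages))


def schedule_protocol(stages: Sequence[tuple[str, float]] | None = None) -> ProtocolSchedule:
    """Build (and validate) a session schedule; ``None`` -> the 42-min default."""
    return ProtocolSchedule(stages=tuple(stages) if stages else DEFAULT_STAGES)
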