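"""Seeded synthetic EEG sessions and longitudinal scale-score cohorts.

No recordings or raw questionnaire data from the motivating study are publicly
deposited, so every downstream stage (denoising, classification, feedback,
statistics) is exercised on simulations with known ground truth:

* clean EEG whose theta/alpha/beta band powers depend on a hidden 0.5-s
  emotion state (``active`` / ``passive`` / ``normal``),
* additive contamination (ocular blinks, mains line noise, white sensor
  noise) kept separately so denoising quality metrics have an exact
  reference, and
* per-group longitudinal SCL-90 / SDS / PHQ-9 score trajectories shaped like
  the study's feedback-training and control groups.

Everything is deterministic under an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .recording import DEFAULT_MONTAGE, EEGRecording

__all__ = [
    "STATES",
    "Band",
    "BandProfile",
    "SessionTruth",
    "ScaleCohort",
    "GROUP_SIZES",
    "gen_clean_eeg",
    "contaminate",
    "simulate_session",
    "gen_scale_cohort",
    "gen_study_cohort",
]

#: The three decoded emotion states of the feedback protocol.
STATES = ("active", "passive", "normal")

WINDOW_S = 0.5  # length of one emotion-state character window


@dataclass(frozen=True)
class Band:
    """A frequency band with one amplitude (µV RMS) per emotion state."""

    lo_hz: float
    hi_hz: float
    amps_uv: Mapping[str, float]

    def amp(self, state: str) -> float:
        return float(self.amps_uv[state])


@dataclass(frozen=True)
class BandProfile:
    """State-dependent band amplitudes plus a 1/f background level.

    The default makes states separable the way affective-EEG conventions
    suggest: beta power is elevated in the ``active`` state, alpha power in
    the ``passive`` state, and ``normal`` sits between the two. Amplitudes
    are RMS in µV and form a geometric ladder (4, 8, 16) so that adjacent
    states are equidistant in log band power — the scale on which spectral
    classifiers operate.
    """

    bands: Mapping[str, Band] = field(
        default_factory=lambda: {
            "theta": Band(4.0, 8.0, {"active": 4.0, "passive": 4.0, "normal": 4.0}),
            "alpha": Band(8.0, 13.0, {"active": 4.0, "passive": 16.0, "normal": 8.0}),
            "beta": Band(13.0, 30.0, {"active": 16.0, "passive": 4.0, "normal": 8.0}),
        }
    )
    background_rms_uv: float = 2.0

    @classmethod
    def silent(cls) -> "BandProfile":
        """All-zero profile (useful to test the generator's linearity)."""
        zero = {s: 0.0 for s in STATES}
        return cls(
            bands={
                "theta": Band(4.0, 8.0, zero),
                "alpha": Band(8.0, 13.0, zero),
                "beta": Band(13.0, 30.0, zero),
            },
            background_rms_uv=0.0,
        )


@dataclass
class SessionTruth:
    """A contaminated session with exact additive ground truth.

    ``noisy.data == clean.data + artifacts.data`` sample-wise; ``state_labels``
    carries one emotion state per 0.5-s window; ``blink_times`` records the
    onset (s) of every simulated ocular transient.
    """

    clean: EEGRecording
    noisy: EEGRecording
    artifacts: EEGRecording
    state_labels: tuple[str, ...]
    seed: int
    blink_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        resid = self.noisy.data - (self.clean.data + self.artifacts.data)
        if np.max(np.abs(resid)) > 1e-9:
            raise ValueError("additivity violated: clean + artifacts != noisy")
        n_expected = int(self.clean.duration_s / WINDOW_S)
        if len(self.state_labels) != n_expected:
            raise ValueError(
                f"expected {n_expected} state labels for {self.clean.duration_s} s, "
                f"got {len(self.state_labels)}"
            )
        bad = set(self.state_labels) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi) Hz via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f-amplitude background noise with the requested RMS in µV."""
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n=n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def gen_clean_eeg(
    n_channels: int = 3,
    duration_s: float = 60.0,
    fs: float = 250.0,
    state_sequence: Sequence[str] | None = None,
    band_profile: BandProfile | None = None,
    seed: int = 0,
    spatial_blend: float = 0.3,
) -> EEGRecording:
    """Generate artifact-free, state-dependent oscillatory EEG.

    Each channel is a sum of band-limited noise carriers (one per band in the
    profile) whose per-window RMS amplitude follows the window's emotion
    state, plus a 1/f background. A 25-ms raised-cosine crossfade smooths the
    amplitude envelope at window boundaries.

    Parameters
    ----------
    state_sequence
        One state per 0.5-s window, length ``duration_s / 0.5``. Defaults to
        all ``"normal"``.
    spatial_blend
        Volume-conduction model: each band has one shared cortical carrier
        seen by every channel through a random gain in [0.7, 1.0], blended
        with a channel-specific carrier at this relative weight. 0 makes
        channels perfectly rank-1 per band; 1 makes them independent. The
        default 0.3 mimics the strong inter-electrode correlation of a
        frontal montage.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if fs < 100:
        raise ValueError("sampling rate below 100 Hz cannot resolve the beta band")
    n_windows = duration_s / WINDOW_S
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError("duration_s must be a multiple of 0.5 s")
    n_windows = int(round(n_windows))
    if state_sequence is None:
        state_sequence = ("normal",) * n_windows
    if len(state_sequence) != n_windows:
        raise ValueError(f"need {n_windows} states, got {len(state_sequence)}")
    profile = band_profile if band_profile is not None else BandProfile()

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    win_len = int(round(WINDOW_S * fs))
    ramp = min(int(0.025 * fs), win_len // 2)

    data = np.zeros((n_channels, n))
    for band in profile.bands.values():
        shared = _band_limited_noise(rng, n, fs, band.lo_hz, band.hi_hz)
        gains = rng.uniform(0.7, 1.0, size=n_channels)
        env = np.repeat([band.amp(s) for s in state_sequence], win_len).astype(float)
        if ramp > 1:
            kernel = np.hanning(2 * ramp + 1)
            kernel /= kernel.sum()
            env = np.convolve(env, kernel, mode="same")
        for ch in range(n_channels):
            own = _band_limited_noise(rng, n, fs, band.lo_hz, band.hi_hz)
            carrier = (1.0 - spatial_blend) * gains[ch] * shared + spatial_blend * own
            data[ch] += env * carrier
    for ch in range(n_channels):
        data[ch] += _pink_noise(rng, n, fs, profile.background_rms_uv)

    labels = tuple(DEFAULT_MONTAGE[i] if i < len(DEFAULT_MONTAGE) else f"EEG{i}" for i in range(n_channels))
    return EEGRecording(data=data, fs=fs, channel_labels=labels)


def _blink_waveform(fs: float, width_s: float = 0.4) -> np.ndarray:
    # raised cosine: zero at the edges, unit peak in the middle
    n = int(round(width_s * fs))
    t = np.arange(n) / fs
    return 0.5 * (1 - np.cos(2 * np.pi * t / width_s))


def contaminate(
    clean: EEGRecording,
    blink_rate_hz: float = 0.2,
    line_freq_hz: float = 50.0,
    noise_sd_uv: float = 2.0,
    seed: int = 0,
    blink_amp_uv: float = 80.0,
    line_amp_uv: float = 10.0,
    frontal_weights: Sequence[float] | None = None,
    state_labels: Sequence[str] | None = None,
) -> SessionTruth:
    """Add ocular, mains and sensor noise to a clean recording.

    Blinks are Poisson-timed 400-ms raised-cosine transients of
    ``blink_amp_uv`` peak amplitude, weighted per channel by
    ``frontal_weights`` (all 1.0 by default — the default montage is entirely
    frontal). Line noise is a pure sinusoid at ``line_freq_hz`` with amplitude
    ``line_amp_uv`` (set either amplitude to 0 to disable that artifact);
    sensor noise is white Gaussian with ``noise_sd_uv`` µV standard deviation.
    """
    if noise_sd_uv < 0 or blink_rate_hz < 0:
        raise ValueError("noise_sd_uv and blink_rate_hz must be non-negative")
    rng = np.random.default_rng(seed)
    n_ch, n = clean.data.shape
    fs = clean.fs
    duration = clean.duration_s
    weights = np.ones(n_ch) if frontal_weights is None else np.asarray(frontal_weights, dtype=float)
    if weights.shape != (n_ch,):
        raise ValueError("frontal_weights must have one entry per channel")

    artifacts = np.zeros_like(clean.data)

    blink_times: list[float] = []
    if blink_rate_hz > 0 and blink_amp_uv != 0:
        wave = _blink_waveform(fs)
        n_events = rng.poisson(blink_rate_hz * duration)
        onsets = np.sort(rng.uniform(0, max(duration - 0.4, 0), size=n_events))
        for onset in onsets:
            i0 = int(round(onset * fs))
            seg = wave[: n - i0]
            amp = blink_amp_uv * rng.uniform(0.8, 1.2)
            artifacts[:, i0 : i0 + len(seg)] += amp * np.outer(weights, seg)
            blink_times.append(float(onset))

    if line_amp_uv != 0 and line_freq_hz > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        artifacts += line_amp_uv * np.sin(2 * np.pi * line_freq_hz * t + phase)[None, :]

    if noise_sd_uv > 0:
        artifacts += rng.normal(0.0, noise_sd_uv, size=(n_ch, n))

    noisy = clean.copy_with(clean.data + artifacts)
    labels = (
        tuple(state_labels)
        if state_labels is not None
        else ("normal",) * int(duration / WINDOW_S)
    )
    return SessionTruth(
        clean=clean,
        noisy=noisy,
        artifacts=clean.copy_with(artifacts),
        state_labels=labels,
        seed=seed,
        blink_times=tuple(blink_times),
    )


def simulate_session(
    n_channels: int = 3,
    duration_s: float = 60.0,
    fs: float = 250.0,
    seed: int = 0,
    state_probs: Mapping[str, float] | None = None,
    band_profile: BandProfile | None = None,
    block_windows: int = 12,
    **contamination,
) -> SessionTruth:
    """Generate a full contaminated session with a random state sequence.

    States are drawn per block of ``block_windows`` 0.5-s windows (default 12,
    i.e. one 6-s music-decision block) so that decoded sequences have the
    run-length structure the segment-decision stage expects.
    """
    rng = np.random.default_rng(seed)
    n_windows = int(round(duration_s / WINDOW_S))
    probs = state_probs or {"active": 1 / 3, "passive": 1 / 3, "normal": 1 / 3}
    p = np.array([probs.get(s, 0.0) for s in STATES], dtype=float)
    p /= p.sum()
    n_blocks = -(-n_windows // block_windows)
    block_states = rng.choice(STATES, size=n_blocks, p=p)
    states = tuple(np.repeat(block_states, block_windows)[:n_windows])

    clean = gen_clean_eeg(
        n_channels, duration_s, fs, states, band_profile, seed=int(rng.integers(2**31))
    )
    return contaminate(
        clean, seed=int(rng.integers(2**31)), state_labels=states, **contamination
    )


# ---------------------------------------------------------------------------
# Longitudinal scale-score cohorts
# ---------------------------------------------------------------------------

#: Study group sizes: 4 feedback-training, 8 depression-control, 4 normal-control.
GROUP_SIZES = {"feedback": 4, "depression_control": 8, "normal_control": 4}

N_TESTS = 6  # weekly scale evaluations

# Per-test target means and SDs emulating the study's reported trajectories.
# The study prints tests {1, 2, 3, 4, 6}; test 5 is the midpoint of its
# neighbours. Feedback means decline monotonically; controls are flat.
_SCALE_TARGETS: dict[str, dict[str, tuple[list[float], list[float]]]] = {
    "scl90": {
        "feedback": ([31.40, 29.75, 28.04, 24.30, 20.75, 17.20], [5.10, 2.33, 1.60, 1.75, 2.30, 2.87]),
        "depression_control": ([31.53, 31.83, 31.14, 31.23, 31.00, 30.82], [5.66, 6.30, 4.52, 5.09, 4.80, 3.16]),
        "normal_control": ([2.74, 2.37, 2.75, 2.60, 2.40, 2.12], [3.19, 2.96, 3.18, 3.16, 2.70, 2.12]),
    },
    "sds": {
        "feedback": ([56.75, 55.42, 50.59, 46.50, 42.02, 37.54], [2.41, 2.48, 3.57, 2.14, 3.90, 5.79]),
        "depression_control": ([56.77, 56.42, 56.64, 56.79, 56.50, 56.30], [2.58, 2.12, 2.55, 2.54, 2.55, 2.58]),
        "normal_control": ([34.37, 33.91, 34.00, 34.19, 34.20, 34.30], [5.92, 5.72, 5.93, 5.75, 5.80, 5.91]),
    },
    "phq9": {
        "feedback": ([6.37, 6.00, 4.72, 3.79, 3.00, 2.24], [1.09, 1.22, 1.59, 0.80, 0.95, 1.08]),
        "depression_control": ([6.38, 6.39, 6.39, 6.44, 6.40, 6.38], [1.26, 1.21, 1.33, 1.14, 1.20, 1.21]),
        "normal_control": ([1.25, 1.27, 1.29, 1.14, 1.20, 1.25], [1.37, 1.36, 1.38, 1.31, 1.35, 1.37]),
    },
}

# Admissible score ranges (the SDS column is treated as an opaque 0-100 index).
_SCALE_RANGES = {"scl90": (0.0, 90.0), "sds": (0.0, 100.0), "phq9": (0.0, 27.0)}

# Baseline enrolment criteria per group: (lo, hi) per scale. Mild-depression
# groups need SCL-90 > 26, SDS in [53, 62], PHQ-9 in [5, 9]; normal controls
# need SCL-90 < 8, SDS < 53, PHQ-9 < 5.
_BASELINE_CRITERIA = {
    "feedback": {"scl90": (26.0 + 1e-6, 90.0), "sds": (53.0, 62.0), "phq9": (5.0, 9.0)},
    "depression_control": {"scl90": (26.0 + 1e-6, 90.0), "sds": (53.0, 62.0), "phq9": (5.0, 9.0)},
    "normal_control": {"scl90": (0.0, 8.0 - 1e-6), "sds": (0.0, 53.0 - 1e-6), "phq9": (0.0, 5.0 - 1e-6)},
}


@dataclass
class ScaleCohort:
    """Longitudinal SCL-90 / SDS / PHQ-9 scores, long format.

    ``scores`` has columns ``subject, group, test_index, scl90, sds, phq9``
    with exactly six test occasions per subject.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "group", "test_index", "scl90", "sds", "phq9"}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValueError(f"cohort is missing columns: {sorted(missing)}")
        counts = self.scores.groupby("subject")["test_index"].nunique()
        if not (counts == N_TESTS).all():
            raise ValueError("every subject needs exactly 6 test occasions")
        for scale, (lo, hi) in _SCALE_RANGES.items():
            vals = self.scores[scale]
            if (vals < lo).any() or (vals > hi).any():
                raise ValueError(f"{scale} scores outside admissible range [{lo}, {hi}]")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.scores["group"].unique())

    def group_scores(self, group: str, scale: str, test_index: int) -> np.ndarray:
        sel = (self.scores["group"] == group) & (self.scores["test_index"] == test_index)
        return self.scores.loc[sel, scale].to_numpy()

    @classmethod
    def combine(cls, *cohorts: "ScaleCohort") -> "ScaleCohort":
        return cls(pd.concat([c.scores for c in cohorts], ignore_index=True))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_scale_cohort(
    group: str,
    n_subjects: int | None = None,
    trend: float = 1.0,
    seed: int = 0,
) -> ScaleCohort:
    """Draw one group's six-visit score trajectories.

    ``trend`` scales the decline of the per-test target means relative to the
    baseline mean: 1.0 reproduces the study-like trajectory (declining for
    the feedback group, flat for controls), 0.0 holds every mean at baseline.
    Draws are truncated normals — to the group's enrolment criteria at
    baseline, to the scale's admissible range afterwards.
    """
    if group not in GROUP_SIZES:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(GROUP_SIZES)}")
    if n_subjects is None:
        n_subjects = GROUP_SIZES[group]
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    rng = np.random.default_rng(seed)

    rows = []
    subj_ids = [f"{group}_{i:02d}" for i in range(n_subjects)]
    values: dict[str, np.ndarray] = {}
    for scale in _SCALE_TARGETS:
        means, sds = _SCALE_TARGETS[scale][group]
        lo_rng, hi_rng = _SCALE_RANGES[scale]
        cols = []
        for t in range(N_TESTS):
            mean_t = means[0] - trend * (means[0] - means[t])
            if t == 0:
                lo, hi = _BASELINE_CRITERIA[group][scale]
            else:
                lo, hi = lo_rng, hi_rng
            cols.append(_truncated_normal(rng, mean_t, sds[t], lo, hi, n_subjects))
        values[scale] = np.column_stack(cols)

    for i, subj in enumerate(subj_ids):
        for t in range(N_TESTS):
            rows.append(
                {
                    "subject": subj,
                    "group": group,
                    "test_index": t + 1,
                    "scl90": values["scl90"][i, t],
                    "sds": values["sds"][i, t],
                    "phq9": values["phq9"][i, t],
                }
            )
    return ScaleCohort(pd.DataFrame(rows))


def gen_study_cohort(trend: float = 1.0, seed: int = 0) -> ScaleCohort:
    """All three groups at their study sizes (4 / 8 / 4 subjects)."""
    rng = np.random.default_rng(seed)
    parts = [
        gen_scale_cohort(g, trend=trend, seed=int(rng.integers(2**31)))
        for g in GROUP_SIZES
    ]
    return ScaleCohort.combine(*parts)
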