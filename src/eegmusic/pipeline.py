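"""End-to-end closed-loop pipeline: simulate -> denoise -> classify -> music.

One :class:`PipelineConfig` drives the whole loop on synthetic data with
ground truth: a contaminated session is simulated, denoised, windowed into
0.5-s windows, classified into emotion states by the CNN and
gradient-boosting models (trained on a matched, independently seeded
training session), aggregated into 6-s music decisions, and rendered as
symbolic music. The report compares the decoded state sequence against the
simulation's ground truth.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import boosting, cnn, feedback
from . import io as eio
from .preprocessing import DenoiseParams, denoise, mape, mean_energy, snir
from .recording import EEGRecording
from .synth import SessionTruth, simulate_session

__all__ = ["PipelineConfig", "run_pipeline", "train_session_models"]


@dataclass
class PipelineConfig:
    """Every knob of one closed-loop run (validated on construction)."""

    n_channels: int = 3
    duration_s: float = 60.0
    train_duration_s: float = 120.0
    fs: float = 250.0
    seed: int = 0
    # contamination of the simulated sessions
    blink_rate_hz: float = 0.2
    line_freq_hz: float = 50.0
    noise_sd_uv: float = 2.0
    # denoising
    denoise_method: str = "EMD_FastICA"
    # classification
    theta_lo: float = 0.4
    theta_hi: float = 0.6
    cnn_epochs: int = 120
    cnn_learning_rate: float = 0.01
    cnn_filters: tuple[int, ...] = (8, 16, 32, 64)
    cnn_dropout_p: float = 0.2
    gb_features: str = "bandpower"  # bandpower | cnn | time
    gb_iterations: int = 20
    gb_shrinkage: float = 0.1
    # protocol
    protocol_stages: tuple[tuple[str, float], ...] = feedback.DEFAULT_STAGES

    def __post_init__(self) -> None:
        if not self.theta_lo < self.theta_hi:
            raise ValueError("theta_lo must be below theta_hi")
        if self.duration_s <= 0 or (self.duration_s / 0.5) % 1:
            raise ValueError("duration_s must be a positive multiple of 0.5")
        if self.gb_features not in ("cnn", "bandpower", "time"):
            raise ValueError(f"unknown gb_features {self.gb_features!r}")
        feedback.schedule_protocol(self.protocol_stages)  # enforces the 45-min cap


def _binary_windows(session: SessionTruth, rec: EEGRecording):
    """Active/passive windows of a (denoised) session with 0/1 labels."""
    windows = rec.windows(0.5)
    labels = np.asarray(session.state_labels[: len(windows)])
    sel = np.isin(labels, ("active", "passive"))
    y = (labels[sel] == "active").astype(int)
    return windows[sel], y


def _gb_featurizer(config: PipelineConfig, cnn_model: cnn.CNNModel | None, fs: float):
    if config.gb_features == "cnn":
        if cnn_model is None:
            raise ValueError("gb_features='cnn' requires a trained CNN")
        return lambda w: cnn_model.features(np.asarray(w, dtype=float))[:, None, :]
    if config.gb_features == "bandpower":
        return lambda w: boosting.bandpower_features(w, fs)
    return lambda w: boosting.time_indexed_features(w)


def _fit_calibration(config: PipelineConfig, session, rec, cnn_model, gb_model, featurize) -> dict:
    """Per-model temperature factors maximizing ternary agreement on the
    (fully labelled) training session.

    Classifiers trained to convergence are over-confident; without
    temperature scaling the mid-range band of the dual-threshold rule is
    never populated and ``normal`` windows cannot be decoded. The grid is
    coarse on purpose — only the order of magnitude matters.
    """
    truth = np.asarray(session.state_labels)
    gb_grid = np.linspace(0.02, 1.0, 25)
    cnn_grid = np.concatenate([[0.0], np.geomspace(0.002, 0.3, 20)])
    best = (-1.0, {"gb": 1.0, "cnn": 1.0})
    thresholds = (config.theta_lo, config.theta_hi)
    p_gb_raw, _ = feedback.window_scores(rec, gb_model=gb_model, gb_featurizer=featurize)
    p_cnn_raw, _ = feedback.window_scores(rec, cnn_model=cnn_model)
    from eegmusic.feedback import _calibrated  # temperature transform

    for cg in gb_grid:
        pg = _calibrated(p_gb_raw, cg)
        for cc in cnn_grid:
            s = 0.5 * (pg + _calibrated(p_cnn_raw, cc))
            agr = float(np.mean(feedback.scores_to_states(s, thresholds) == truth))
            if agr > best[0]:
                best = (agr, {"gb": float(cg), "cnn": float(cc)})
    return best[1]


def train_session_models(config: PipelineConfig, train_seed: int):
    """Simulate a matched training session, fit both classifiers, calibrate.

    Returns ``(cnn_model, gb_model, featurizer, calibration)`` where
    ``calibration`` holds the per-model temperature factors fitted on the
    training session's ground-truth ternary labels.
    """
    session = simulate_session(
        n_channels=config.n_channels,
        duration_s=config.train_duration_s,
        fs=config.fs,
        seed=train_seed,
        blink_rate_hz=config.blink_rate_hz,
        line_freq_hz=config.line_freq_hz,
        noise_sd_uv=config.noise_sd_uv,
    )
    den = denoise(session.noisy, config.denoise_method, DenoiseParams(line_freq_hz=config.line_freq_hz))
    X, y = _binary_windows(session, den)
    specs = cnn.default_architecture(filters=config.cnn_filters, dropout_p=config.cnn_dropout_p)
    cnn_model = cnn.train_cnn(
        X, y, specs=specs, epochs=config.cnn_epochs,
        learning_rate=config.cnn_learning_rate, seed=train_seed,
    )
    featurize = _gb_featurizer(config, cnn_model, config.fs)
    gb_model = boosting.train_gb(
        featurize(X), y, M=config.gb_iterations, shrinkage=config.gb_shrinkage
    )
    calibration = _fit_calibration(config, session, den, cnn_model, gb_model, featurize)
    return cnn_model, gb_model, featurize, calibration


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full loop; optionally write all artifacts to ``outdir``.

    Returns the session report: denoising metrics, window agreement with
    ground truth, segment decisions and music fragment counts.
    """
    rng = np.random.default_rng(config.seed)
    eval_seed, train_seed, music_seed = (int(s) for s in rng.integers(2**31, size=3))

    session = simulate_session(
        n_channels=config.n_channels,
        duration_s=config.duration_s,
        fs=config.fs,
        seed=eval_seed,
        blink_rate_hz=config.blink_rate_hz,
        line_freq_hz=config.line_freq_hz,
        noise_sd_uv=config.noise_sd_uv,
    )
    den = denoise(session.noisy, config.denoise_method, DenoiseParams(line_freq_hz=config.line_freq_hz))

    cnn_model, gb_model, featurize, calibration = train_session_models(config, train_seed)

    seq = feedback.classify_windows(
        den, cnn_model, gb_model,
        thresholds=(config.theta_lo, config.theta_hi),
        gb_featurizer=featurize,
        calibration=calibration,
    )
    agreement = float(np.mean(np.asarray(seq.labels) == np.asarray(session.state_labels)))
    decisions = feedback.segment_decision(seq)
    segments = feedback.render_session(decisions, seed=music_seed)
    counts = {v: decisions.count(v) for v in feedback.VALENCES}

    report = {
        "seed": config.seed,
        "denoise_method": config.denoise_method,
        "snir_db": snir(session.clean.data, session.noisy.data, den.data),
        "mean_energy_uv2": mean_energy(den.data),
        "mape_pct": mape(session.clean.data, den.data),
        "window_agreement": agreement,
        "n_windows": len(seq),
        "n_segments": len(decisions),
        "n_markers": feedback.marker_count(len(decisions)),
        "music_counts": counts,
        "calibration": calibration,
        "protocol_total_min": feedback.schedule_protocol(config.protocol_stages).total_min,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        eio.write_eeg(session.noisy, outdir / "session_noisy.csv")
        eio.write_eeg(den, outdir / "session_denoised.csv")
        eio.write_labels(session.state_labels, outdir / "truth_labels.csv")
        eio.write_labels(seq.labels, outdir / "decoded_labels.csv")
        eio.write_music_events(segments, outdir / "music_events.csv")
        cnn_model.save(outdir / "cnn_model.json")
        gb_model.save(outdir / "gb_model.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
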