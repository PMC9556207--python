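"""Denoising quality metrics: SNIR, mean energy, MAPE.

SNIR is the signal-to-noise *improvement* ratio of a denoiser, reported in
decibels as the difference between output and input SNR:

    SNIR = SNR_out(dB) - SNR_in(dB),   SNR(dB) = 10 log10(P_signal / P_noise)

with input noise ``noisy - clean`` and residual output noise
``denoised - clean``. The signal power cancels, so SNIR reduces to
``10 log10(P_noise_in / P_noise_out)``; positive values mean the denoiser
helped. Mean energy is the average squared amplitude of the denoised signal
(µV² for µV input — the motivating tables label the column µV, a unit slip we
do not repeat). MAPE is the mean absolute percentage error of the
reconstruction against the clean reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DenoisingReport", "snir", "mean_energy", "mape", "SNIR_SATURATION_DB"]

#: Returned by :func:`snir` when the denoiser output is exactly the clean
#: signal (zero residual noise power); keeps downstream arithmetic finite.
SNIR_SATURATION_DB = 300.0


@dataclass
class DenoisingReport:
    """One method's row of a denoising comparison table."""

    method: str
    snir_db: float
    mean_energy: float  # µV²
    mape_pct: float

    def __post_init__(self) -> None:
        if self.mape_pct < 0 or self.mean_energy < 0:
            raise ValueError("mean energy and MAPE are non-negative by definition")


def _flat(x) -> np.ndarray:
    a = np.asarray(getattr(x, "data", x), dtype=float)
    return a.ravel()


def snir(clean, noisy, denoised) -> float:
    """Signal-to-noise improvement in dB (see module docstring).

    Raises ``ValueError`` when the input noise power is zero (the metric is
    undefined: there was nothing to denoise). A perfect reconstruction
    returns :data:`SNIR_SATURATION_DB`.
    """
    c, y, d = _flat(clean), _flat(noisy), _flat(denoised)
    if not (len(c) == len(y) == len(d)):
        raise ValueError("clean, noisy and denoised must have equal lengths")
    p_in = float(np.mean((y - c) ** 2))
    if p_in == 0.0:
        raise ValueError("input noise power is zero; SNIR is undefined")
    p_out = float(np.mean((d - c) ** 2))
    if p_out == 0.0:
        return SNIR_SATURATION_DB
    return 10.0 * np.log10(p_in / p_out)


def mean_energy(signal) -> float:
    """Average squared amplitude ``(1/n) sum x_i^2`` (µV² for µV input)."""
    x = _flat(signal)
    if len(x) == 0:
        raise ValueError("mean_energy of an empty signal is undefined")
    return float(np.mean(x**2))


def mape(actual, denoised, zero_frac: float = 0.01) -> float:
    """Mean absolute percentage error, in percent.

    Samples where ``|actual|`` falls below ``zero_frac`` times the reference
    RMS are excluded with a warning: the relative error is undefined at zero
    and, for zero-mean oscillatory signals, sub-noise-floor samples otherwise
    dominate the average with physically meaningless ratios. (EEG crosses
    zero constantly, so some exclusion always occurs.)
    """
    a, f = _flat(actual), _flat(denoised)
    if len(a) != len(f):
        raise ValueError("signals must have equal lengths")
    if len(a) == 0:
        raise ValueError("MAPE of empty signals is undefined")
    rms = float(np.sqrt(np.mean(a**2)))
    mask = np.abs(a) >= max(zero_frac * rms, 1e-12)
    if not mask.all():
        warnings.warn(
            f"MAPE: excluded {int((~mask).sum())} near-zero reference samples",
            stacklevel=2,
        )
    if not mask.any():
        raise ValueError("all reference samples are (near-)zero; MAPE undefined")
    return float(np.mean(np.abs(a[mask] - f[mask]) / np.abs(a[mask])) * 100.0)
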