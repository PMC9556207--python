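"""Empirical mode decomposition by classic envelope sifting.

Huang-style sifting: cubic-spline upper/lower envelopes through the local
extrema (mirror-extended at the boundaries), iterated until the Cauchy
standard-deviation criterion falls below a threshold, peeling off intrinsic
mode functions (IMFs) fast-to-slow until the residue is monotonic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["IMFSet", "sift_imfs"]


@dataclass
class IMFSet:
    """Ordered IMFs (fast to slow) plus the monotonic-ish residue.

    ``sum(imfs) + residue`` reconstructs the input exactly (the residue is
    computed by subtraction, so reconstruction holds to float round-off).
    """

    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima.

    Plateaus are forward-filled with the preceding slope sign so a flat-top
    peak registers exactly one extremum (at its right edge).
    """
    s = np.sign(np.diff(x))
    nz = np.flatnonzero(s)
    if len(nz) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    fill = np.zeros(len(s), dtype=int)
    fill[nz] = nz
    np.maximum.accumulate(fill, out=fill)
    filled = s[fill]
    filled[: nz[0]] = s[nz[0]]
    ds = np.diff(filled)
    maxima = np.flatnonzero(ds < 0) + 1  # slope flips + -> -
    minima = np.flatnonzero(ds > 0) + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s)))


def _is_imf(x: np.ndarray) -> bool:
    mx, mn = _local_extrema(x)
    return abs((len(mx) + len(mn)) - _zero_crossings(x)) <= 1


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through ``x[idx]`` with mirrored end extrema."""
    k = min(2, len(idx))
    left_t = -idx[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    # mirrored points can coincide with boundary extrema; deduplicate
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    if len(t) < 2:
        return np.full(n, v[0])
    if len(t) < 4:  # CubicSpline needs >= 4 points for a cubic; fall back to linear
        return np.interp(np.arange(n), t, v)
    return CubicSpline(t, v, bc_type="natural")(np.arange(n))


def sift_imfs(signal: np.ndarray, max_imfs: int = 10, sd_stop: float = 0.2, max_siftings: int = 10) -> IMFSet:
    """Decompose a 1-D signal into IMFs plus a residue.

    Parameters
    ----------
    signal
        1-D array, at least 8 samples, all finite.
    max_imfs
        Upper bound on the number of IMFs extracted.
    sd_stop
        Cauchy criterion threshold: sifting of one IMF stops when
        ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below this value (and
        the IMF extrema/zero-crossing criterion holds), or after
        ``max_siftings`` passes.

    A monotonic input yields no IMFs — the whole signal is the residue.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("sift_imfs expects a 1-D signal")
    if len(x) < 8:
        raise ValueError("signal too short to sift (need >= 8 samples)")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    n = len(x)
    for _ in range(max_imfs):
        mx, mn = _local_extrema(residue)
        if len(mx) < 2 or len(mn) < 2:
            break  # residue has no oscillation left to sift
        h = residue.copy()
        sifted = False
        for _ in range(max_siftings):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            upper = _envelope(h, mx, n)
            lower = _envelope(h, mn, n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            sifted = True
            if sd < sd_stop and _is_imf(h):
                break
        if not sifted or _zero_crossings(h) == 0:
            break  # non-oscillatory tail belongs in the residue
        imfs.append(h)
        residue = residue - h
    return IMFSet(imfs=imfs, residue=residue)
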