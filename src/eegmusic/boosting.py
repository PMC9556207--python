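"""Gradient boosting with a logistic link and time-indexed OLS weak learners.

The strong classifier is an additive score ``F_m = F_{m-1} + eps * gamma_m *
f_m`` built stagewise to maximize the Bernoulli log-likelihood

    L(F) = sum_i [ y_i log p(F_i) + (1 - y_i) log(1 - p(F_i)) ],
    p(F) = e^F / (e^F + e^{-F}) = logistic(2F),

so the preset ``F_0 = 0`` gives ``p = 0.5`` everywhere. Each stage fits an
ordinary-least-squares projection ``f(o_i) = a^T o_i(t)`` of the sample's
feature vector at one time index ``t`` to the pseudo-residuals
``2 (y_i - p_{m-1,i})`` (the gradient of L), picks the ``(a, t)`` with
minimum squared error, line-searches the stage weight ``gamma`` (L is
concave in ``gamma``), and shrinks it by ``eps`` for generalization.

Features are arrays of shape ``(n_samples, n_times, n_dims)``: one
``n_dims``-vector per candidate time index per sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "WeakLearner",
    "GBModel",
    "predict_proba",
    "gb_log_likelihood",
    "pseudo_residuals",
    "fit_weak_learner",
    "line_search_gamma",
    "train_gb",
    "time_indexed_features",
    "bandpower_features",
]

_CLIP = 1e-12


def predict_proba(F: np.ndarray) -> np.ndarray:
    """``p(y=1) = e^F / (e^F + e^-F)``, i.e. the logistic of ``2F``, stably."""
    F = np.asarray(F, dtype=float)
    # logistic(2F) with sign-split for numerical stability
    out = np.empty_like(F)
    pos = F >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-2.0 * F[pos]))
    e = np.exp(2.0 * F[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def gb_log_likelihood(F: np.ndarray, labels: np.ndarray) -> float:
    """Bernoulli log-likelihood of scores ``F`` (probabilities clipped at 1e-12)."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(predict_proba(F), _CLIP, 1.0 - _CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def pseudo_residuals(labels: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Negative gradient of the loss w.r.t. F: ``2 (y - p)``."""
    return 2.0 * (np.asarray(labels, dtype=float) - np.asarray(probs, dtype=float))


@dataclass(frozen=True)
class WeakLearner:
    """One boosting stage: projection direction ``a`` at time index ``t``."""

    a: np.ndarray
    t: int
    gamma: float = 0.0

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float)[:, self.t, :] @ self.a


def fit_weak_learner(features: np.ndarray, residuals: np.ndarray) -> tuple[np.ndarray, int, float]:
    """Best OLS projection of one time slice onto the residuals.

    For each candidate time index ``t`` solve ``min_a sum_i (r_i - a^T
    o_i(t))^2`` and return ``(a, t, sse)`` for the minimizing ``t`` (smallest
    ``t`` on ties). A singular design at some ``t`` falls back to a tiny
    ridge (lambda = 1e-8) with a warning.
    """
    X = np.asarray(features, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if X.ndim != 3:
        raise ValueError("features must be (n_samples, n_times, n_dims)")
    n, n_times, d = X.shape
    if n < 2 or n_times < 1:
        raise ValueError("need at least 2 samples and 1 time index")
    best: tuple[np.ndarray, int, float] | None = None
    for t in range(n_times):
        O = X[:, t, :]
        gram = O.T @ O
        rhs = O.T @ r
        try:
            a = np.linalg.solve(gram, rhs)
            if not np.isfinite(a).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(f"singular design at t={t}; ridge fallback", stacklevel=2)
            a = np.linalg.solve(gram + 1e-8 * np.eye(d), rhs)
        sse = float(np.sum((r - O @ a) ** 2))
        if best is None or sse < best[2] - 1e-12:
            best = (a, t, sse)
    return best


def line_search_gamma(F_prev: np.ndarray, f_out: np.ndarray, labels: np.ndarray) -> float:
    """Stage weight maximizing ``L(F_prev + gamma * f_out)``.

    L is concave in gamma for this link, so a bounded 1-D maximization over
    ``[-10, 10]`` suffices. All-zero weak-learner output returns 0 with a
    warning; the returned gamma never decreases the likelihood (falls back
    to 0 otherwise).
    """
    f = np.asarray(f_out, dtype=float)
    if not np.any(f):
        warnings.warn("weak learner output is identically zero; gamma = 0", stacklevel=2)
        return 0.0
    L0 = gb_log_likelihood(F_prev, labels)

    res = minimize_scalar(
        lambda g: -gb_log_likelihood(F_prev + g * f, labels),
        bounds=(-10.0, 10.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    gamma = float(res.x)
    if gb_log_likelihood(F_prev + gamma * f, labels) < L0 - 1e-12:
        return 0.0
    return gamma


@dataclass
class GBModel:
    """Trained boosted classifier: ordered stages plus shrinkage and F0."""

    learners: list[WeakLearner] = field(default_factory=list)
    shrinkage: float = 0.1
    F0: float = 0.0
    likelihood_history: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.learners)

    @property
    def trained(self) -> bool:
        return bool(self.learners)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        F = np.full(X.shape[0], self.F0)
        for wl in self.learners:
            F += self.shrinkage * wl.gamma * wl(X)
        return F

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return predict_proba(self.decision_function(features))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_proba(features) > 0.5).astype(int)

    def to_dict(self) -> dict:
        return {
            "shrinkage": self.shrinkage,
            "F0": self.F0,
            "likelihood_history": self.likelihood_history,
            "learners": [
                {"a": wl.a.tolist(), "t": int(wl.t), "gamma": wl.gamma} for wl in self.learners
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GBModel":
        return cls(
            learners=[WeakLearner(np.asarray(l["a"]), l["t"], l["gamma"]) for l in d["learners"]],
            shrinkage=d["shrinkage"],
            F0=d["F0"],
            likelihood_history=list(d["likelihood_history"]),
        )

    @classmethod
    def load(cls, path) -> "GBModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_gb(
    features: np.ndarray,
    labels: np.ndarray,
    M: int = 100,
    shrinkage: float = 0.1,
    min_gain: float = 1e-8,
) -> GBModel:
    """Stagewise boosting for up to ``M`` iterations.

    Training stops early once the likelihood gain of a stage falls below
    ``min_gain``. The likelihood history is non-decreasing: shrinkage keeps
    each step on the concave ascent path between 0 and the line-search
    optimum. Deterministic (no randomness is involved).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")

    model = GBModel(shrinkage=shrinkage, F0=0.0)
    F = np.full(X.shape[0], model.F0)
    L = gb_log_likelihood(F, y)
    model.likelihood_history.append(L)
    if shrinkage == 0.0:
        return model  # degenerate: scores stay at F0, p = 0.5 everywhere
    for _ in range(M):
        p = predict_proba(F)
        r = pseudo_residuals(y, p)
        a, t, _ = fit_weak_learner(X, r)
        f_out = X[:, t, :] @ a
        gamma = line_search_gamma(F, f_out, y)
        if gamma == 0.0:
            break
        F = F + shrinkage * gamma * f_out
        L_new = gb_log_likelihood(F, y)
        model.learners.append(WeakLearner(a, t, gamma))
        model.likelihood_history.append(L_new)
        if L_new - L < min_gain:
            break
        L = L_new
    return model


def bandpower_features(
    windows: np.ndarray,
    fs: float,
    bands: tuple[tuple[float, float], ...] = ((4.0, 8.0), (8.0, 13.0), (13.0, 30.0)),
) -> np.ndarray:
    """EEG windows ``(B, C, S)`` -> log band-power features ``(B, 1, C * n_bands)``.

    A single "time index" whose feature vector is the log mean periodogram
    power of each channel in each band — the nonlinearity that lets linear
    weak learners separate states differing in oscillatory power.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3:
        raise ValueError("windows must be (batch, channels, samples)")
    n = w.shape[2]
    spec = np.abs(np.fft.rfft(w, axis=2)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    feats = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi)
        feats.append(np.log(spec[:, :, sel].mean(axis=2) + 1e-12))
    out = np.concatenate(feats, axis=1)  # (B, C * n_bands)
    return out[:, None, :]


def time_indexed_features(windows: np.ndarray, decim: int = 5) -> np.ndarray:
    """EEG windows ``(B, C, S)`` -> boosting features ``(B, T, C)``.

    Each candidate time index is one decimated sample position; the feature
    vector there is the per-channel amplitudes.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3:
        raise ValueError("windows must be (batch, channels, samples)")
    return w[:, :, ::decim].transpose(0, 2, 1)
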