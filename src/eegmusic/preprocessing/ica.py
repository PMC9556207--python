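"""FastICA: symmetric fixed-point independent component analysis.

Implements the classic tanh-contrast fixed-point iteration with PCA
whitening and symmetric decorrelation. Written in-house so that tests can
cross-check it against an independent reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ICADecomposition", "fast_ica", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Raised when the centered data matrix cannot support the requested rank."""


@dataclass
class ICADecomposition:
    """Result of a FastICA run.

    ``sources = unmixing @ whitener @ (data - mean)`` and ``mixing`` is the
    pseudo-inverse of ``unmixing @ whitener``, so
    ``mixing @ sources + mean`` reconstructs the data (exactly when the
    decomposition is full rank).
    """

    sources: np.ndarray       # (n_components, n_samples)
    unmixing: np.ndarray      # (n_components, n_components), acts on whitened data
    mixing: np.ndarray        # (n_channels, n_components)
    whitener: np.ndarray      # (n_components, n_channels)
    mean: np.ndarray          # (n_channels,)
    converged: bool
    iterations: int

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Back-project sources to sensor space, optionally zeroing components.

        ``keep`` is a boolean mask over components; dropped components are
        zeroed before back-projection (artifact rejection).
        """
        s = self.sources if keep is None else self.sources * np.asarray(keep, bool)[:, None]
        return self.mixing @ s + self.mean[:, None]


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^(-1/2) W via eigendecomposition
    vals, vecs = np.linalg.eigh(w @ w.T)
    vals = np.clip(vals, 1e-12, None)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T @ w


def fast_ica(
    data: np.ndarray,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> ICADecomposition:
    """Separate linearly mixed independent sources.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` matrix.
    n_components
        Number of components to extract; defaults to the numerical rank of
        the centered data (at most ``n_channels``).

    Raises
    ------
    RankDeficientError
        If ``n_components`` exceeds the numerical rank of the centered data.

    A run that hits ``max_iter`` without meeting ``tol`` returns the best
    iterate with ``converged=False`` rather than raising.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n = x.shape
    mean = x.mean(axis=1)
    xc = x - mean[:, None]

    cov = (xc @ xc.T) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-10))
    if n_components is None:
        n_components = rank
    if n_components > n_ch or n_components > rank:
        raise RankDeficientError(
            f"requested {n_components} components but centered data has numerical rank {rank}"
        )
    whitener = (evecs[:, :n_components] / np.sqrt(evals[:n_components])).T
    z = whitener @ xc  # whitened: cov(z) == I

    rng = np.random.default_rng(seed)
    w = _sym_decorrelate(rng.standard_normal((n_components, n_components)))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wz = w @ z
        g = np.tanh(wz)
        g_prime = 1.0 - g**2
        w_new = (g @ z.T) / n - np.diag(g_prime.mean(axis=1)) @ w
        w_new = _sym_decorrelate(w_new)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0)))
        w = w_new
        if lim < tol:
            converged = True
            break

    sources = w @ z
    mixing = np.linalg.pinv(w @ whitener)
    return ICADecomposition(
        sources=sources,
        unmixing=w,
        mixing=mixing,
        whitener=whitener,
        mean=mean,
        converged=converged,
        iterations=it,
    )
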