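"""Lag threads: spatial PCA of the column-centered time-delay matrix.

A single propagation sequence makes the column-centered TD matrix rank
one (every centered column is the centered delay field). Multiple
simultaneous propagation sequences make the measured pairwise lag a
nonlinear mixture of the underlying delay fields, and the centered TD
matrix acquires as many dominant spatial components — the *lag
threads*. The number of statistically supported threads is estimated by
Minka's Laplace-approximation Bayesian model selection over candidate
PCA dimensionalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .lagcore import TimeDelayMatrix

__all__ = [
    "ThreadDecomposition",
    "lag_threads",
    "ml_dimensionality",
    "laplace_evidence",
]


@dataclass
class ThreadDecomposition:
    """Eigenvalues, thread topographies, and ML dimensionality."""

    eigenvalues: np.ndarray       # descending, nonnegative
    components: np.ndarray        # (n, k) topographies, seconds, up to sign
    eigenvectors: np.ndarray      # (n, k) unit-norm spatial eigenvectors
    dimensionality_ml: int
    n_columns_used: int


def laplace_evidence(spectrum: np.ndarray, k: int, n_obs: int) -> float:
    """Log Laplace evidence of a k-dimensional PCA model (Minka's form).

    ``spectrum`` holds the eigenvalues of the sample covariance
    (descending, positive); ``n_obs`` is the number of observations the
    covariance was estimated from. ``k = 0`` is the isotropic-noise
    model.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    d = spectrum.size
    if not 0 <= k < d:
        raise ValueError("need 0 <= k < len(spectrum)")
    n = n_obs

    pu = -k * np.log(2.0)
    for i in range(1, k + 1):
        pu += gammaln((d - i + 1) / 2.0) - ((d - i + 1) / 2.0) * np.log(np.pi)

    pl = -0.5 * n * np.log(spectrum[:k]).sum() if k else 0.0
    v = max(spectrum[k:].sum() / (d - k), np.finfo(float).eps)
    pv = -0.5 * n * (d - k) * np.log(v)

    m = d * k - k * (k + 1) / 2.0
    pp = 0.5 * (m + k) * np.log(2.0 * np.pi)

    filled = spectrum.copy()
    filled[k:] = v
    pa = 0.0
    for i in range(k):
        for j in range(i + 1, d):
            pa += np.log(
                (spectrum[i] - spectrum[j]) * (1.0 / filled[j] - 1.0 / filled[i])
            ) + np.log(n)

    return pu + pl + pv + pp - 0.5 * pa - 0.5 * k * np.log(n)


def ml_dimensionality(
    eigenvalues: np.ndarray, n_obs: int, k_max: int | None = None
) -> int:
    """Maximum-likelihood (maximum-evidence) PCA dimensionality.

    Trims non-positive eigenvalues, scores every candidate dimensionality
    ``k = 0 .. k_max`` by the Laplace evidence, and returns the argmax.
    Requires at least two usable eigenvalues.
    """
    spectrum = np.asarray(eigenvalues, dtype=float)
    spectrum = spectrum[spectrum > 0]
    d = spectrum.size
    if d < 2:
        raise ValueError("need at least 2 positive eigenvalues")
    if n_obs <= d:
        # evidence is still computable; candidates are capped below n_obs
        pass
    hi = d - 1 if k_max is None else min(k_max, d - 1)
    scores = [laplace_evidence(spectrum, k, n_obs) for k in range(hi + 1)]
    return int(np.argmax(scores))


def lag_threads(td: TimeDelayMatrix, k_max: int = 10) -> ThreadDecomposition:
    """Decompose a TD matrix into lag threads.

    Invalid entries are imputed with their column mean (equivalently
    zero after centering — the least-informative completion). Each
    column is then zero-centered and treated as one observation of an
    n-dimensional spatial variable; the eigendecomposition of their
    covariance gives the thread topographies. Components are scaled by
    the RMS projection amplitude (sqrt of the eigenvalue), which has
    units of seconds.
    """
    n = td.n
    if n < 3:
        raise ValueError("need at least 3 voxels")
    M = np.where(td.validity, td.td, np.nan)
    col_mean = np.nanmean(np.where(np.isnan(M), np.nan, M), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    M = np.where(np.isnan(M), col_mean[None, :], M)
    Mc = M - M.mean(axis=0, keepdims=True)
    cov = (Mc @ Mc.T) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(k_max, n)
    if (evals > 0).sum() < 2:
        dim = 0  # no spectrum to select over (e.g. an all-zero TD)
    else:
        dim = ml_dimensionality(evals, n_obs=n, k_max=min(k_max, evals.size - 1))
    components = evecs[:, :k] * np.sqrt(evals[:k])[None, :]
    return ThreadDecomposition(
        eigenvalues=evals,
        components=components,
        eigenvectors=evecs[:, :k],
        dimensionality_ml=dim,
        n_columns_used=n,
    )
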