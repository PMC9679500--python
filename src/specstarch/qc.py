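"""Exploratory PCA and Mahalanobis-distance outlier removal.

With many more wavelengths than samples the raw covariance is singular,
so distances are computed in a retained principal-component score space
(components covering 99% cumulative variance, capped at n-2) and scaled
so the removal threshold behaves like an SD rule regardless of how many
components are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spectra_io import SpectraSet

__all__ = ["PCAResult", "pca_spectra", "mahalanobis_filter"]


@dataclass
class PCAResult:
    scores: np.ndarray              # (n, k)
    loadings: np.ndarray            # (p, k)
    explained_variance_ratio: np.ndarray  # (k,), non-increasing, sums <= 1
    singular_values: np.ndarray     # all min(n, p) singular values

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("invalid explained-variance proportions")


def pca_spectra(spectra: SpectraSet, n_components: int) -> PCAResult:
    """Column-mean-centred PCA of the reflectance matrix via SVD.

    Loadings signs are fixed (largest-magnitude element positive) so
    repeated runs agree exactly rather than up to a sign flip.
    """
    X = spectra.reflectance
    n, p = X.shape
    if n < 2:
        raise ConfigError("PCA requires at least 2 samples")
    if n_components > min(n - 1, p):
        raise ConfigError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total = float(np.sum(S**2))
    evr = (S**2 / total) if total > 0 else np.zeros_like(S)
    scores = U[:, :n_components] * S[:n_components]
    return PCAResult(
        scores=scores,
        loadings=Vt[:n_components].T,
        explained_variance_ratio=evr[:n_components],
        singular_values=S,
    )


def mahalanobis_filter(
    spectra: SpectraSet,
    threshold: float = 3.0,
    variance_covered: float = 0.99,
) -> tuple[SpectraSet, list, pd.Series]:
    """Remove spectra whose scaled Mahalanobis distance exceeds ``threshold``.

    The distance of row i is ``sqrt(mean_k (score_ik / sd_k)^2)`` over the
    k retained components: a chi-style distance divided by ``sqrt(k)`` so
    the default threshold of 3 acts like a 3-SD rule whatever k is.

    Returns
    -------
    (kept, removed_ids, distances)
        ``kept`` preserves input row order; ``distances`` is indexed by
        ``sample_id`` for every input row.
    """
    n = spectra.n_samples
    ids = spectra.meta["sample_id"]
    if n < 3:
        warnings.warn("fewer than 3 samples: outlier QC skipped", stacklevel=2)
        return spectra.copy(), [], pd.Series(np.zeros(n), index=ids, name="distance")

    full = pca_spectra(spectra, n_components=min(n - 2, spectra.reflectance.shape[1]))
    cum = np.cumsum(full.explained_variance_ratio)
    k = int(np.searchsorted(cum, variance_covered) + 1)
    k = max(1, min(k, full.scores.shape[1]))
    scores = full.scores[:, :k]
    sd = np.std(scores, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = scores / sd
    distances = np.sqrt(np.mean(z**2, axis=1))

    outlier = distances > threshold
    removed_ids = ids[outlier].tolist()
    kept = spectra.take(np.flatnonzero(~outlier))
    return kept, removed_ids, pd.Series(distances, index=ids, name="distance")
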