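"""Wavelength-importance profiling: VIP for PLSR, permutation for any model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .models import CalibrationModel, predict

__all__ = ["ImportanceProfile", "vip_scores", "permutation_importance", "top_wavelengths"]


@dataclass
class ImportanceProfile:
    wavelengths: np.ndarray
    scores: np.ndarray
    method: str
    model_algorithm: str
    scores_se: np.ndarray | None = None  # Monte-Carlo SE (permutation only)

    def __post_init__(self) -> None:
        if len(self.wavelengths) != len(self.scores):
            raise DataError("wavelengths and scores differ in length")
        if not np.all(np.isfinite(self.scores)):
            raise DataError("importance scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength": self.wavelengths, "score": self.scores, "method": self.method}
        )


def vip_scores(model: CalibrationModel) -> ImportanceProfile:
    """Variable importance in projection over the model's selected rank.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a't_a, the response variance captured by component a.
    The squared scores average to exactly 1 across wavelengths.
    """
    if model.algorithm != "PLSR" or model.plsr is None:
        raise ConfigError("VIP is defined for PLSR models only")
    state = model.plsr
    rank = model.selected_rank or state.weights.shape[1]
    rank = min(rank, state.weights.shape[1])
    if rank < 1:
        raise ConfigError("VIP requires at least one PLS component")
    W = state.weights[:, :rank]
    ssy = state.q[:rank] ** 2 * state.score_ssq[:rank]
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 / wnorm2) @ ssy / ssy.sum())
    return ImportanceProfile(np.asarray(model.wavelengths), vip, "VIP", "PLSR")


def permutation_importance(
    model: CalibrationModel,
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10,
    seed: int = 0,
) -> ImportanceProfile:
    """Mean RMSE increase when one wavelength column is shuffled.

    Seeded and deterministic; a column carrying no information scores
    near zero (it can be slightly negative by chance).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    base = float(np.sqrt(np.mean((predict(model, X) - y) ** 2)))
    scores = np.zeros(X.shape[1])
    ses = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        deltas = np.empty(n_perm)
        for b in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            deltas[b] = np.sqrt(np.mean((predict(model, Xp) - y) ** 2)) - base
        scores[j] = deltas.mean()
        ses[j] = deltas.std(ddof=1) / np.sqrt(n_perm) if n_perm > 1 else float("nan")
    return ImportanceProfile(
        np.asarray(model.wavelengths), scores, "permutation", model.algorithm,
        scores_se=ses,
    )


def top_wavelengths(profile: ImportanceProfile, k: int) -> list[int]:
    """Top-k wavelengths by score; ties broken by ascending wavelength."""
    if k > len(profile.wavelengths):
        raise ConfigError("k exceeds the number of wavelengths")
    order = np.lexsort((profile.wavelengths, -profile.scores))
    return [int(profile.wavelengths[i]) for i in order[:k]]
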