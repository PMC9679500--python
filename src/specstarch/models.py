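"""Calibration models: first-party PLSR plus SVM/RF delegates.

PLSR is implemented from scratch (NIPALS with deflation) because rank
selection, loadings and the VIP importance scores all depend on its
internal state.  Radial-kernel support-vector regression and random
forests delegate to scikit-learn behind the same fit/predict contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .errors import ConfigError, DataError, FitError
from .spectra_io import SpectraSet

__all__ = [
    "ALGORITHMS",
    "PLSRState",
    "CalibrationModel",
    "fit_plsr",
    "fit_delegate",
    "predict",
    "select_hyperparameters",
    "grouped_kfold",
]

ALGORITHMS = ("PLSR", "SVM_RADIAL", "RF")

DEFAULT_MAX_RANK = 10
DEFAULT_SVM_GRID = {"C": (1.0, 10.0, 100.0), "gamma": ("scale", 0.01)}
DEFAULT_RF_GRID = {"n_estimators": (200,), "max_features": (0.1, 0.33, 1.0)}


@dataclass
class PLSRState:
    """Internal NIPALS factorization, kept per rank.

    ``weights`` W and ``loadings`` P are (p, A); ``q`` holds the
    y-loadings and ``score_ssq`` the t'a t_a norms.  ``coefs`` stores the
    regression vector for every rank 0..A, so one fit serves all ranks.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    q: np.ndarray
    score_ssq: np.ndarray
    coefs: np.ndarray  # (A+1, p); row r is the rank-r regression vector
    scores: np.ndarray | None = None  # (n, A) training score vectors


@dataclass
class CalibrationModel:
    """Fitted predictor with a uniform contract across algorithms."""

    algorithm: str
    wavelengths: np.ndarray
    pretreatment: str = "RAW"
    hyperparams: dict = field(default_factory=dict)
    plsr: PLSRState | None = None
    delegate: Any = None
    selected_rank: int | None = None

    def predict(self, X: np.ndarray | SpectraSet) -> np.ndarray:
        return predict(self, X)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int,
             pretreatment: str = "RAW",
             wavelengths: np.ndarray | None = None) -> CalibrationModel:
    """Mean-centred NIPALS partial least squares for a univariate response.

    Stores the regression vector for every rank up to ``n_components``
    (truncated early if the residual covariance vanishes).  Deterministic
    given the row order of the inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DataError("X and y have different numbers of rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("missing values in X or y")
    if n_components < 0 or n_components > min(n - 1, p):
        raise ConfigError(f"n_components must lie in [0, min(n-1, p)] = [0, {min(n - 1, p)}]")
    if np.std(y) == 0:
        raise FitError("constant response: PLSR fit is undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ssq = np.zeros(n_components)
    actual = 0
    for a in range(n_components):
        cov = E.T @ f
        norm = np.linalg.norm(cov)
        if norm < 1e-14:
            break
        w = cov / norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pa = (E.T @ t) / tt
        qa = float(f @ t) / tt
        W[:, a], P[:, a], q[a], ssq[a] = w, pa, qa, tt
        T[:, a] = t
        E = E - np.outer(t, pa)
        f = f - qa * t
        actual += 1

    W, P, q, ssq = W[:, :actual], P[:, :actual], q[:actual], ssq[:actual]
    T = T[:, :actual]
    coefs = np.zeros((actual + 1, p))
    if actual:
        # B_r = W_r (P_r' W_r)^-1 q_r for every rank r
        PtW = P.T @ W
        for r in range(1, actual + 1):
            coefs[r] = W[:, :r] @ np.linalg.solve(PtW[:r, :r], q[:r])

    state = PLSRState(x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P,
                      q=q, score_ssq=ssq, coefs=coefs, scores=T)
    return CalibrationModel(
        algorithm="PLSR",
        wavelengths=np.arange(p) if wavelengths is None else np.asarray(wavelengths),
        pretreatment=pretreatment,
        hyperparams={"n_components": actual},
        plsr=state,
        selected_rank=actual,
    )


def fit_delegate(X: np.ndarray, y: np.ndarray, algorithm: str,
                 hyperparams: dict | None = None, seed: int = 0,
                 pretreatment: str = "RAW",
                 wavelengths: np.ndarray | None = None) -> CalibrationModel:
    """Fit an SVM (radial kernel) or random-forest delegate."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    hp = dict(hyperparams or {})
    if algorithm == "SVM_RADIAL":
        est = SVR(kernel="rbf", C=hp.get("C", 10.0), gamma=hp.get("gamma", "scale"))
    elif algorithm == "RF":
        est = RandomForestRegressor(
            n_estimators=int(hp.get("n_estimators", 200)),
            max_features=hp.get("max_features", 0.33),
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ConfigError(f"unknown delegate algorithm {algorithm!r}")
    est.fit(X, y)
    return CalibrationModel(
        algorithm=algorithm,
        wavelengths=np.arange(X.shape[1]) if wavelengths is None else np.asarray(wavelengths),
        pretreatment=pretreatment,
        hyperparams=hp,
        delegate=est,
    )


def predict(model: CalibrationModel, X: np.ndarray | SpectraSet) -> np.ndarray:
    """Predict starch from spectra on the model's training grid."""
    if isinstance(X, SpectraSet):
        if not np.array_equal(X.wavelengths, model.wavelengths):
            raise DataError("wavelength grid does not match the training grid")
        X = X.reflectance
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.wavelengths):
        raise DataError(
            f"expected {len(model.wavelengths)} wavelength columns, got {X.shape[1]}"
        )
    if model.algorithm == "PLSR":
        state = model.plsr
        rank = model.selected_rank if model.selected_rank is not None else state.coefs.shape[0] - 1
        rank = min(rank, state.coefs.shape[0] - 1)
        return state.y_mean + (X - state.x_mean) @ state.coefs[rank]
    return np.asarray(model.delegate.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# Hyperparameter selection
# ---------------------------------------------------------------------------

def grouped_kfold(groups: Sequence, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random k-fold partition of row indices keeping each group intact."""
    groups = np.asarray(groups)
    unique = pd.unique(groups)
    if k > len(unique):
        raise ConfigError(f"k={k} exceeds the number of groups ({len(unique)})")
    order = rng.permutation(len(unique))
    folds: list[list[int]] = [[] for _ in range(k)]
    by_group = {g: np.flatnonzero(groups == g) for g in unique}
    for j, gi in enumerate(order):
        folds[j % k].extend(by_group[unique[gi]])
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _r2cv(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def select_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    k: int = 5,
    seed: int = 0,
    groups: Sequence | None = None,
    max_rank: int = DEFAULT_MAX_RANK,
    svm_grid: dict | None = None,
    rf_grid: dict | None = None,
) -> dict:
    """Grid search by k-fold RMSECV; returns the winner and its CV profile.

    The partition is a seeded random k-fold grouped by ``groups`` when
    given (otherwise each row is its own group).  Selection is plain
    minimum RMSECV; ties go to the simpler setting (lower rank / earlier
    grid entry).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2 * k:
        raise ConfigError(f"need at least 2k={2 * k} samples for {k}-fold tuning")
    if algorithm not in ALGORITHMS:
        raise ConfigError(f"unknown algorithm {algorithm!r}")
    rng = np.random.default_rng(seed)
    grp = np.arange(n) if groups is None else np.asarray(groups)
    folds = grouped_kfold(grp, k, rng)

    if algorithm == "PLSR":
        cap = min(max_rank, min(n - 1, X.shape[1]))
        cv_pred = np.full((cap + 1, n), np.nan)
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            fold_cap = min(cap, int(mask.sum()) - 1)
            model = fit_plsr(X[mask], y[mask], n_components=fold_cap)
            state = model.plsr
            Xt = X[test_idx] - state.x_mean
            for r in range(cap + 1):
                rr = min(r, state.coefs.shape[0] - 1)
                cv_pred[r, test_idx] = state.y_mean + Xt @ state.coefs[rr]
        profile = pd.DataFrame(
            {
                "n_components": np.arange(1, cap + 1),
                "rmsecv": [_rmse(y, cv_pred[r]) for r in range(1, cap + 1)],
                "r2cv": [_r2cv(y, cv_pred[r]) for r in range(1, cap + 1)],
            }
        )
        best = int(profile["rmsecv"].idxmin())
        return {
            "algorithm": "PLSR",
            "chosen": {"n_components": int(profile.loc[best, "n_components"])},
            "rmsecv": float(profile.loc[best, "rmsecv"]),
            "r2cv": float(profile.loc[best, "r2cv"]),
            "profile": profile,
        }

    if algorithm == "SVM_RADIAL":
        grid = svm_grid or DEFAULT_SVM_GRID
        candidates = [{"C": c, "gamma": g} for c in grid["C"] for g in grid["gamma"]]
    else:
        grid = rf_grid or DEFAULT_RF_GRID
        candidates = [
            {"n_estimators": t, "max_features": m}
            for t in grid["n_estimators"]
            for m in grid["max_features"]
        ]

    records = []
    best_hp, best_rmse, best_r2 = None, np.inf, 0.0
    for hp in candidates:
        cv_pred = np.full(n, np.nan)
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            model = fit_delegate(X[mask], y[mask], algorithm, hp, seed=seed)
            cv_pred[test_idx] = predict(model, X[test_idx])
        r = _rmse(y, cv_pred)
        records.append({**hp, "rmsecv": r, "r2cv": _r2cv(y, cv_pred)})
        if r < best_rmse:
            best_hp, best_rmse, best_r2 = hp, r, records[-1]["r2cv"]
    return {
        "algorithm": algorithm,
        "chosen": best_hp,
        "rmsecv": best_rmse,
        "r2cv": best_r2,
        "profile": pd.DataFrame(records),
    }
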