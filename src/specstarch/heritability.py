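"""REML variance components and broad-sense heritability.

Two field-design models are supported, both with a fixed intercept and
independent normal random effects:

* RCBD:           value = mean + genotype + block + residual
* alpha-lattice:  value = mean + genotype + replicate + block(replicate)
                          + residual

Estimation profiles the residual variance out of the restricted
likelihood and optimizes the remaining variance ratios under a
nonnegativity bound (L-BFGS-B, then a Nelder-Mead polish).  On balanced
designs the estimates coincide with the classical ANOVA
method-of-moments solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .errors import DesignError
from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "VarianceComponents",
    "fit_rcbd",
    "fit_alpha_lattice",
    "broad_sense_h2",
    "spectral_heritability_scan",
    "trait_heritability",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    n_rep: float
    sigma2_rep: float = float("nan")
    sigma2_block: float = float("nan")
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_e"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.n_rep < 1:
            raise DesignError("n_rep must be >= 1")


def _incidence(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), codes.max() + 1))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z


def _reml(y: np.ndarray, Z_list: list[np.ndarray], x0: np.ndarray | None = None,
          tol: float = 1e-8, max_iter: int = 500, polish: bool = True):
    """Profile REML for y = mu + sum_i u_i + e; returns (sigma2s, sigma2_e,
    loglik, converged, ratios)."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    m = len(Z_list)
    G = [Z @ Z.T for Z in Z_list]
    ones = np.ones(n)

    if np.allclose(y, y[0]):
        return np.zeros(m), 0.0, float("nan"), True, np.zeros(m)

    def negloglik(gamma: np.ndarray) -> float:
        gamma = np.clip(gamma, 0.0, None)
        V = np.eye(n)
        for g, Gi in zip(gamma, G):
            if g > 0:
                V = V + g * Gi
        try:
            c, low = cho_factor(V, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e30
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        vi_y = cho_solve((c, low), y, check_finite=False)
        vi_1 = cho_solve((c, low), ones, check_finite=False)
        xtvx = float(ones @ vi_1)
        beta = float(ones @ vi_y) / xtvx
        r = y - beta
        quad = float(r @ cho_solve((c, low), r, check_finite=False))
        s2 = max(quad / (n - 1), 1e-300)
        return 0.5 * ((n - 1) * math.log(s2) + logdet_v + math.log(xtvx))

    start = np.ones(m) if x0 is None else np.clip(np.asarray(x0, dtype=float), 0.0, None)
    bounds = [(0.0, 1e8)] * m
    res = optimize.minimize(
        negloglik, start, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": max_iter},
    )
    best = res
    if polish:
        res2 = optimize.minimize(
            negloglik, res.x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": tol * 1e-2, "fatol": 1e-14, "maxiter": max_iter * 4},
        )
        if res2.fun <= res.fun:
            best = res2
    gamma = np.clip(best.x, 0.0, None)

    # recompute sigma2_e and the restricted log-likelihood at the optimum
    V = np.eye(n)
    for g, Gi in zip(gamma, G):
        V = V + g * Gi
    c, low = cho_factor(V, check_finite=False)
    vi_y = cho_solve((c, low), y, check_finite=False)
    vi_1 = cho_solve((c, low), ones, check_finite=False)
    xtvx = float(ones @ vi_1)
    beta = float(ones @ vi_y) / xtvx
    r = y - beta
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    s2 = quad / (n - 1)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    loglik = -0.5 * (
        (n - 1) * (math.log(2 * math.pi * max(s2, 1e-300)) + 1.0)
        + logdet_v
        + math.log(xtvx)
    )
    sigmas = gamma * s2
    return sigmas, s2, loglik, bool(res.success), gamma


def _mean_reps(genotype) -> float:
    counts = pd.Series(genotype).value_counts()
    return float(counts.mean())


def fit_rcbd(values, genotype, block, polish: bool = True,
             x0: np.ndarray | None = None) -> VarianceComponents:
    """REML for the RCBD model with random genotype and block effects."""
    values = np.asarray(values, dtype=float)
    genotype = np.asarray(genotype)
    block = np.asarray(block)
    if not (len(values) == len(genotype) == len(block)):
        raise DesignError("values, genotype and block must have equal length")
    if pd.Series(genotype).nunique() < 2:
        raise DesignError("RCBD fit needs at least 2 genotypes")
    sigmas, s2e, ll, ok, _ = _reml(
        values, [_incidence(genotype), _incidence(block)], x0=x0, polish=polish
    )
    return VarianceComponents(
        sigma2_g=float(sigmas[0]), sigma2_block=float(sigmas[1]), sigma2_e=float(s2e),
        n_rep=_mean_reps(genotype), converged=ok, loglik=ll,
    )


def fit_alpha_lattice(values, genotype, rep, block_within_rep,
                      polish: bool = True,
                      x0: np.ndarray | None = None) -> VarianceComponents:
    """REML for the alpha-lattice model: genotype, replicate and
    block-nested-in-replicate random effects.

    ``block_within_rep`` labels are interpreted within each replicate;
    the nested factor is the (rep, block) combination.
    """
    values = np.asarray(values, dtype=float)
    genotype = np.asarray(genotype)
    rep = np.asarray(rep)
    block = np.asarray(block_within_rep)
    if not (len(values) == len(genotype) == len(rep) == len(block)):
        raise DesignError("all label vectors must match the number of values")
    if pd.Series(genotype).nunique() < 2:
        raise DesignError("alpha-lattice fit needs at least 2 genotypes")
    nested = np.array([f"{r}::{b}" for r, b in zip(rep, block)])
    sigmas, s2e, ll, ok, _ = _reml(
        values, [_incidence(genotype), _incidence(rep), _incidence(nested)],
        x0=x0, polish=polish,
    )
    return VarianceComponents(
        sigma2_g=float(sigmas[0]), sigma2_rep=float(sigmas[1]),
        sigma2_block=float(sigmas[2]), sigma2_e=float(s2e),
        n_rep=_mean_reps(genotype), converged=ok, loglik=ll,
    )


def broad_sense_h2(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability on the 0-100 scale:
    ``100 * s2_g / (s2_g + s2_e / nRep)``; NaN when both variances are 0."""
    denom = vc.sigma2_g + vc.sigma2_e / vc.n_rep
    if denom == 0:
        return float("nan")
    return 100.0 * vc.sigma2_g / denom


def _fit_trial(values, sub: pd.DataFrame, polish: bool,
               x0: np.ndarray | None = None) -> VarianceComponents:
    design = sub["design"].iloc[0]
    if design == "RCBD":
        return fit_rcbd(values, sub["genotype_id"], sub["block"], polish=polish, x0=x0)
    return fit_alpha_lattice(values, sub["genotype_id"], sub["rep"], sub["block"],
                             polish=polish, x0=x0)


def trait_heritability(reference: ReferenceTable) -> pd.DataFrame:
    """Per-trial variance components and H-squared of the starch trait."""
    rows = []
    for trial_id in reference.trials:
        sub = reference.trial(trial_id)
        vc = _fit_trial(sub["starch"].to_numpy(dtype=float), sub, polish=True)
        rows.append(
            {
                "trial_id": trial_id,
                "sigma2_g": vc.sigma2_g,
                "sigma2_rep": vc.sigma2_rep,
                "sigma2_block": vc.sigma2_block,
                "sigma2_e": vc.sigma2_e,
                "n_rep": vc.n_rep,
                "h2": broad_sense_h2(vc),
                "converged": vc.converged,
            }
        )
    return pd.DataFrame(rows)


def spectral_heritability_scan(spectra: SpectraSet,
                               reference: ReferenceTable) -> pd.DataFrame:
    """Fit the trial-appropriate model at every wavelength independently.

    ``spectra`` must be plot level (one row per sample, scans averaged).
    Non-convergence at a wavelength is recorded and the scan continues.
    Consecutive wavelengths warm-start from each other but results do not
    depend on execution order beyond the optimizer's starting point.
    """
    ref = reference.data.set_index("sample_id")
    rows = []
    for trial_id in reference.trials:
        sub_ids = [s for s in spectra.meta["sample_id"] if s in ref.index
                   and ref.loc[s, "trial_id"] == trial_id]
        if not sub_ids:
            continue
        trial_spectra = spectra.select_samples(sub_ids)
        sub = ref.loc[trial_spectra.meta["sample_id"]].reset_index()
        x0 = None
        for j, wl in enumerate(trial_spectra.wavelengths):
            values = trial_spectra.reflectance[:, j]
            try:
                vc = _fit_trial(values, sub, polish=False, x0=x0)
                h2 = broad_sense_h2(vc)
                converged = vc.converged
            except Exception:
                vc, h2, converged = None, float("nan"), False
            if vc is not None and vc.sigma2_e > 0:
                ratios = [vc.sigma2_g / vc.sigma2_e]
                if not math.isnan(vc.sigma2_rep):
                    ratios.append(vc.sigma2_rep / vc.sigma2_e)
                ratios.append(vc.sigma2_block / vc.sigma2_e)
                x0 = np.array(ratios)
            rows.append(
                {
                    "trial_id": trial_id,
                    "wavelength": int(wl),
                    "sigma2_g": vc.sigma2_g if vc else float("nan"),
                    "sigma2_e": vc.sigma2_e if vc else float("nan"),
                    "h2": h2,
                    "converged": converged,
                }
            )
    return pd.DataFrame(rows)
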