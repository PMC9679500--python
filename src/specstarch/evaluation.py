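"""Validation engine: grouped resampling, the metric suite, CV schemes.

Within-trial evaluation repeats a genotype-grouped 70/30 split (50
iterations by default) with 5-fold hyperparameter tuning inside the
training set.  Four additional schemes cross tested/untested genotypes
with tested/untested environments:

* CV2  - 30% of a focal trial's genotypes form the test set; everything
  else (including those genotypes' plots in other trials) trains.
* CV1  - same test sets as CV2, but the test genotypes are removed from
  the training set entirely.
* CV0  - an entire focal trial is the test set; all other trials train.
* CV00 - like CV0, but test-set genotypes are removed from training.

CV1/CV2 are repeated (default 50 iterations); CV0/CV00 are single-shot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SchemeError
from .models import fit_delegate, fit_plsr, predict, select_hyperparameters
from .pretreat import apply_pretreatment
from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "SCHEMES",
    "SplitPlan",
    "EvaluationResult",
    "grouped_split",
    "compute_metrics",
    "within_trial_evaluate",
    "build_cv_scheme",
    "verify_plan",
    "run_cv_schemes",
]

SCHEMES = ("WITHIN_TRIAL", "CV2", "CV1", "CV0", "CV00")

METRIC_COLUMNS = ("r2p", "r2cv", "rmsep", "rmsecv", "sep", "bias", "rpd", "rpiq", "ccc")


@dataclass
class SplitPlan:
    """One train/test partition of plot-level sample ids."""

    scheme: str
    focal_trial: object
    iteration: int
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise SchemeError("train and test sets overlap")


@dataclass
class EvaluationResult:
    """Per-iteration metric table plus mean/SD aggregates."""

    per_iteration: pd.DataFrame
    aggregate: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        metrics = [c for c in METRIC_COLUMNS if c in self.per_iteration.columns]
        self.aggregate = self.per_iteration[metrics].agg(["mean", "std"])


def grouped_split(sample_ids, groups, train_fraction: float = 0.7,
                  seed: int = 0) -> SplitPlan:
    """Random split of whole groups; the fraction applies to group count.

    All plots of a group land on one side.  ``floor(fraction * n_groups)``
    groups train; the remainder tests.
    """
    sample_ids = np.asarray(sample_ids)
    groups = np.asarray(groups)
    unique = pd.unique(groups)
    if len(unique) < 2:
        raise SchemeError("grouped split needs at least 2 groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_train = int(np.floor(train_fraction * len(unique)))
    if n_train < 1 or n_train >= len(unique):
        raise SchemeError("train_fraction leaves an empty train or test set")
    train_groups = set(unique[order[:n_train]])
    in_train = np.array([g in train_groups for g in groups])
    return SplitPlan(
        scheme="WITHIN_TRIAL",
        focal_trial=None,
        iteration=0,
        train_ids=list(sample_ids[in_train]),
        test_ids=list(sample_ids[~in_train]),
        seed=seed,
    )


def compute_metrics(observed, predicted) -> dict:
    """Prediction-quality metric suite on a test set.

    bias = mean(pred - obs); RMSEP = root mean squared residual; SEP =
    sample SD (n-1) of the residuals; RPD = SD(obs)/RMSEP; RPIQ =
    IQR(obs)/RMSEP with linearly interpolated (type-7) quartiles; CCC uses
    n-denominator moments.  Ratios with a zero RMSEP are reported as NaN.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise DataError("observed and predicted lengths differ")
    if obs.size < 3:
        raise DataError("metrics need at least 3 points")
    if np.std(obs) == 0:
        raise DataError("constant observed values: metrics undefined")

    resid = pred - obs
    bias = float(np.mean(resid))
    rmsep = float(np.sqrt(np.mean(resid**2)))
    sep = float(np.std(resid, ddof=1))
    sd_obs = float(np.std(obs, ddof=1))
    q1, q3 = np.percentile(obs, [25, 75])
    iqr = float(q3 - q1)
    if rmsep > 0:
        rpd, rpiq = sd_obs / rmsep, iqr / rmsep
    else:
        rpd = rpiq = float("nan")

    if np.std(pred) == 0:
        r2p = 0.0
    else:
        r2p = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    sxy = float(np.mean((obs - obs.mean()) * (pred - pred.mean())))
    sx2 = float(np.mean((obs - obs.mean()) ** 2))
    sy2 = float(np.mean((pred - pred.mean()) ** 2))
    ccc = 2 * sxy / (sx2 + sy2 + (obs.mean() - pred.mean()) ** 2)

    return {
        "r2p": r2p,
        "rmsep": rmsep,
        "sep": sep,
        "bias": bias,
        "rpd": rpd,
        "rpiq": rpiq,
        "ccc": float(ccc),
    }


def _align(spectra: SpectraSet, reference: ReferenceTable) -> tuple[np.ndarray, pd.DataFrame]:
    """Row-align plot-level spectra with the reference table by sample_id."""
    if "scan_index" in spectra.meta.columns and spectra.meta["sample_id"].duplicated().any():
        raise DataError("spectra contain repeated scans; average_scans first")
    ref = reference.data.set_index("sample_id")
    ids = spectra.meta["sample_id"]
    missing = [s for s in ids if s not in ref.index]
    if missing:
        raise DataError(f"samples without reference values: {missing[:5]}...")
    aligned = ref.loc[ids].reset_index()
    return spectra.reflectance, aligned


def _fit_and_score(X, y, groups, train_idx, test_idx, algorithm, seed,
                   k=5, max_rank=10) -> dict:
    sel = select_hyperparameters(
        X[train_idx], y[train_idx], algorithm, k=k, seed=seed,
        groups=groups[train_idx], max_rank=max_rank,
    )
    if algorithm == "PLSR":
        model = fit_plsr(X[train_idx], y[train_idx], sel["chosen"]["n_components"])
    else:
        model = fit_delegate(X[train_idx], y[train_idx], algorithm, sel["chosen"], seed=seed)
    pred = predict(model, X[test_idx])
    row = compute_metrics(y[test_idx], pred)
    row["r2cv"] = sel["r2cv"]
    row["rmsecv"] = sel["rmsecv"]
    row["hyperparams"] = str(sel["chosen"])
    return row


def within_trial_evaluate(
    spectra: SpectraSet,
    reference: ReferenceTable,
    pretreatment: str = "RAW",
    algorithm: str = "PLSR",
    niter: int = 50,
    seed: int = 0,
    train_fraction: float = 0.7,
    k: int = 5,
    max_rank: int = 10,
) -> EvaluationResult:
    """Repeated genotype-grouped 70/30 evaluation of one sample set."""
    treated = apply_pretreatment(spectra, pretreatment)
    X, aligned = _align(treated, reference)
    y = aligned["starch"].to_numpy(dtype=float)
    groups = aligned["genotype_id"].to_numpy()
    ids = aligned["sample_id"].to_numpy()
    id_to_row = {s: i for i, s in enumerate(ids)}

    seeds = np.random.SeedSequence(seed).generate_state(niter)
    rows = []
    for it in range(niter):
        plan = grouped_split(ids, groups, train_fraction, seed=int(seeds[it]))
        tr = np.array([id_to_row[s] for s in plan.train_ids])
        te = np.array([id_to_row[s] for s in plan.test_ids])
        row = _fit_and_score(X, y, groups, tr, te, algorithm, int(seeds[it]),
                             k=k, max_rank=max_rank)
        row.update({"iteration": it, "pretreatment": pretreatment, "algorithm": algorithm})
        rows.append(row)
    return EvaluationResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Breeder-relevant CV schemes
# ---------------------------------------------------------------------------

def build_cv_scheme(
    scheme: str,
    reference: ReferenceTable,
    focal_trial,
    seed: int = 0,
    niter: int = 50,
    test_fraction: float = 0.3,
) -> list[SplitPlan]:
    """Construct train/test plans for one focal trial under one scheme.

    CV1 and CV2 share identical test sets under a shared seed; CV1 and
    CV00 additionally guarantee zero genotype overlap between train and
    test.  CV0/CV00 return exactly one plan.
    """
    if scheme not in ("CV2", "CV1", "CV0", "CV00"):
        raise SchemeError(f"unknown scheme {scheme!r}")
    data = reference.data
    trials = set(data["trial_id"])
    if focal_trial not in trials:
        raise SchemeError(f"focal trial {focal_trial!r} not present")
    if len(trials) < 2:
        raise SchemeError("CV schemes need at least 2 trials")

    focal = data[data["trial_id"] == focal_trial]
    others = data[data["trial_id"] != focal_trial]
    focal_genotypes = pd.unique(focal["genotype_id"])

    if scheme in ("CV0", "CV00"):
        test_ids = focal["sample_id"].tolist()
        if scheme == "CV0":
            train = others
        else:
            train = others[~others["genotype_id"].isin(set(focal_genotypes))]
        return [SplitPlan(scheme, focal_trial, 0, train["sample_id"].tolist(), test_ids, seed)]

    n_test = int(round(test_fraction * len(focal_genotypes)))
    if n_test < 1 or n_test >= len(focal_genotypes):
        raise SchemeError("test_fraction leaves an empty train or test set")
    plans = []
    seeds = np.random.SeedSequence(seed).generate_state(niter)
    for it in range(niter):
        rng = np.random.default_rng(int(seeds[it]))
        test_genotypes = set(rng.permutation(focal_genotypes)[:n_test])
        test_mask = focal["genotype_id"].isin(test_genotypes)
        test_ids = focal.loc[test_mask, "sample_id"].tolist()
        if scheme == "CV2":
            train = pd.concat([focal.loc[~test_mask], others])
        else:  # CV1: remove the test genotypes everywhere
            pool = pd.concat([focal.loc[~test_mask], others])
            train = pool[~pool["genotype_id"].isin(test_genotypes)]
        plans.append(SplitPlan(scheme, focal_trial, it, train["sample_id"].tolist(),
                               test_ids, seed))
    return plans


def verify_plan(plan: SplitPlan, reference: ReferenceTable,
                test_fraction: float = 0.3) -> None:
    """Programmatic check of the scheme-defining set relations.

    Raises :class:`SchemeError` on any violation; used as a property test.
    """
    data = reference.data.set_index("sample_id")
    train, test = set(plan.train_ids), set(plan.test_ids)
    if train & test:
        raise SchemeError("train/test overlap")
    g_train = set(data.loc[list(train), "genotype_id"])
    g_test = set(data.loc[list(test), "genotype_id"])
    focal = data[data["trial_id"] == plan.focal_trial]
    test_trials = set(data.loc[list(test), "trial_id"])
    if test_trials != {plan.focal_trial}:
        raise SchemeError("test plots must come from the focal trial")

    if plan.scheme in ("CV0", "CV00"):
        if test != set(focal.index):
            raise SchemeError("CV0/CV00 test set must be the entire focal trial")
        if plan.scheme == "CV0":
            expected = set(data[data["trial_id"] != plan.focal_trial].index)
            if train != expected:
                raise SchemeError("CV0 train set must be all other trials")
        if plan.scheme == "CV00" and g_train & g_test:
            raise SchemeError("CV00 requires zero genotype overlap")
    elif plan.scheme in ("CV1", "CV2"):
        n_expected = int(round(test_fraction * focal["genotype_id"].nunique()))
        if len(g_test) != n_expected:
            raise SchemeError(
                f"{plan.scheme} test genotype count {len(g_test)} != {n_expected}"
            )
        # every plot of a test genotype in the focal trial is in the test set
        in_focal = focal[focal["genotype_id"].isin(g_test)]
        if set(in_focal.index) != test:
            raise SchemeError("test genotypes must contribute all their focal plots")
        if plan.scheme == "CV1" and g_train & g_test:
            raise SchemeError("CV1 requires zero genotype overlap")
        if plan.scheme == "CV2":
            expected = set(data.index) - set(in_focal.index)
            if train != expected:
                raise SchemeError("CV2 train set must be all remaining plots")


def run_cv_schemes(
    spectra: SpectraSet,
    reference: ReferenceTable,
    pretreatments=("RAW",),
    algorithms=("PLSR",),
    schemes=("CV2", "CV1", "CV0", "CV00"),
    niter: int = 50,
    seed: int = 0,
    k: int = 5,
    max_rank: int = 10,
) -> pd.DataFrame:
    """Scheme x trial x pretreatment x algorithm evaluation, tidy output."""
    if len(set(reference.data["trial_id"])) < 2:
        raise SchemeError("CV schemes need at least 2 trials")
    rows = []
    for pretreatment in pretreatments:
        treated = apply_pretreatment(spectra, pretreatment)
        X, aligned = _align(treated, reference)
        y = aligned["starch"].to_numpy(dtype=float)
        groups = aligned["genotype_id"].to_numpy()
        id_to_row = {s: i for i, s in enumerate(aligned["sample_id"])}
        for scheme in schemes:
            for trial in reference.trials:
                n_iter = 1 if scheme in ("CV0", "CV00") else niter
                plans = build_cv_scheme(scheme, reference, trial, seed=seed, niter=n_iter)
                for algorithm in algorithms:
                    for plan in plans:
                        tr = np.array([id_to_row[s] for s in plan.train_ids])
                        te = np.array([id_to_row[s] for s in plan.test_ids])
                        row = _fit_and_score(X, y, groups, tr, te, algorithm,
                                             seed, k=k, max_rank=max_rank)
                        row.update(
                            {
                                "scheme": scheme,
                                "trial_id": trial,
                                "iteration": plan.iteration,
                                "pretreatment": pretreatment,
                                "algorithm": algorithm,
                            }
                        )
                        rows.append(row)
    return pd.DataFrame(rows)
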