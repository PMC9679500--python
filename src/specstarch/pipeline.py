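"""End-to-end orchestration: simulate/load -> QC -> evaluate -> profile.

Every stage output is a pure function of (inputs, config, seed).  A run
manifest records the config hash and per-stage seeds so a replay with the
same manifest is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .evaluation import SCHEMES, run_cv_schemes, within_trial_evaluate
from .heritability import spectral_heritability_scan, trait_heritability
from .importance import top_wavelengths, vip_scores
from .models import ALGORITHMS, fit_plsr, select_hyperparameters
from .pretreat import PRETREATMENT_IDS, apply_pretreatment
from .qc import mahalanobis_filter
from .spectra_io import (
    ReferenceTable,
    SpectraSet,
    average_scans,
    read_reference_csv,
    read_spectra_csv,
    summarize_reference,
    trim_wavelengths,
    write_reference_csv,
    write_spectra_csv,
)
from .synthetic import SimulationConfig, simulate_reference, simulate_spectra

logger = logging.getLogger("specstarch")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated end-to-end run configuration.

    Defaults mirror the published analysis settings: 70% calibration
    fraction, 50 resampling iterations, Mahalanobis threshold 3 and
    5-fold tuning.
    """

    spectra_csv: str | None = None
    reference_csv: str | None = None
    simulation: SimulationConfig | None = None
    pretreatments: tuple[str, ...] = ("RAW",)
    algorithms: tuple[str, ...] = ("PLSR",)
    schemes: tuple[str, ...] = ()
    niter: int = 50
    train_fraction: float = 0.7
    mahalanobis_threshold: float = 3.0
    trim_range: tuple[int, int] | None = None
    k_folds: int = 5
    max_rank: int = 10
    top_k_wavelengths: int = 10
    run_heritability: bool = True
    run_importance: bool = True
    seed: int = 0
    output_dir: str = "specstarch_out"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        has_files = self.spectra_csv is not None and self.reference_csv is not None
        if not has_files and self.simulation is None:
            raise ConfigError("provide spectra_csv+reference_csv or a simulation config")
        if not self.pretreatments:
            raise ConfigError("at least one pretreatment is required")
        for p in self.pretreatments:
            if p not in PRETREATMENT_IDS:
                raise ConfigError(f"unknown pretreatment {p!r}")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ConfigError(f"unknown algorithm {a!r}")
        for s in self.schemes:
            if s not in SCHEMES or s == "WITHIN_TRIAL":
                raise ConfigError(f"unknown CV scheme {s!r}")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.niter < 1 or self.k_folds < 2 or self.max_rank < 1:
            raise ConfigError("niter, k_folds and max_rank must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if isinstance(sim, dict):
            d["simulation"] = SimulationConfig.from_dict(sim)
        for key in ("pretreatments", "algorithms", "schemes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("trim_range") is not None:
            d["trim_range"] = tuple(d["trim_range"])
        return cls(**d)


def _config_hash(config: PipelineConfig) -> str:
    # output_dir does not affect results, so it is excluded from the hash
    payload = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("simulate", "evaluate", "schemes", "importance")
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {name: int(s) for name, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write artifacts to the output dir.

    Returns a report bundle (dict) with the manifest and the in-memory
    stage outputs.  Any stage failure raises with the stage name; partial
    artifacts written so far are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stage_seeds": seeds,
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        if config.simulation is not None:
            sim = SimulationConfig.from_dict(
                {**config.simulation.to_dict(), "seed": seeds["simulate"]}
            )
            reference = simulate_reference(sim)
            spectra = simulate_spectra(reference, sim)
            write_reference_csv(reference, out / "reference.csv")
            write_spectra_csv(spectra, out / "spectra.csv")
        else:
            spectra = read_spectra_csv(config.spectra_csv)
            reference = read_reference_csv(config.reference_csv)

        if config.trim_range is not None:
            spectra = trim_wavelengths(spectra, *config.trim_range)

        stage("summarize")
        summary = summarize_reference(reference)
        summary.to_csv(out / "reference_summary.csv")
        bundle["reference_summary"] = summary

        stage("average_scans")
        plot_spectra = average_scans(spectra)

        stage("qc")
        kept, removed, distances = mahalanobis_filter(
            plot_spectra, threshold=config.mahalanobis_threshold
        )
        qc_report = {
            "threshold": config.mahalanobis_threshold,
            "n_in": plot_spectra.n_samples,
            "n_removed": len(removed),
            "removed_ids": list(map(str, removed)),
        }
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        distances.to_csv(out / "qc_distances.csv")
        bundle["qc"] = qc_report
        kept_ref = ReferenceTable(
            reference.data[reference.data["sample_id"].isin(set(kept.meta["sample_id"]))]
        )

        stage("evaluate")
        tables = []
        for pretreatment in config.pretreatments:
            for algorithm in config.algorithms:
                result = within_trial_evaluate(
                    kept, kept_ref, pretreatment, algorithm,
                    niter=config.niter, seed=seeds["evaluate"],
                    train_fraction=config.train_fraction,
                    k=config.k_folds, max_rank=config.max_rank,
                )
                table = result.per_iteration.copy()
                tables.append(table)
        metrics = pd.concat(tables, ignore_index=True)
        metrics.to_csv(out / "within_trial_metrics.csv", index=False)
        bundle["within_trial_metrics"] = metrics

        if config.schemes:
            stage("cv_schemes")
            scheme_table = run_cv_schemes(
                kept, kept_ref, config.pretreatments, config.algorithms,
                schemes=config.schemes, niter=config.niter,
                seed=seeds["schemes"], k=config.k_folds, max_rank=config.max_rank,
            )
            scheme_table.to_csv(out / "cv_scheme_metrics.csv", index=False)
            bundle["cv_scheme_metrics"] = scheme_table

        if config.run_importance:
            stage("importance")
            treated = apply_pretreatment(kept, config.pretreatments[0])
            ref_idx = kept_ref.data.set_index("sample_id")
            y = ref_idx.loc[treated.meta["sample_id"], "starch"].to_numpy(dtype=float)
            sel = select_hyperparameters(
                treated.reflectance, y, "PLSR", k=config.k_folds,
                seed=seeds["importance"],
                groups=treated.meta["genotype_id"].to_numpy()
                if "genotype_id" in treated.meta else None,
                max_rank=config.max_rank,
            )
            model = fit_plsr(
                treated.reflectance, y, sel["chosen"]["n_components"],
                pretreatment=config.pretreatments[0], wavelengths=treated.wavelengths,
            )
            profile = vip_scores(model)
            profile.to_frame().to_csv(out / "importance_vip.csv", index=False)
            top = top_wavelengths(profile, min(config.top_k_wavelengths,
                                               len(profile.wavelengths)))
            (out / "importance_top.json").write_text(
                json.dumps({"method": "VIP", "top_wavelengths": top}, indent=2)
            )
            bundle["importance"] = {"profile": profile, "top": top}

        if config.run_heritability:
            stage("heritability")
            trait_h2 = trait_heritability(kept_ref)
            trait_h2.to_csv(out / "trait_heritability.csv", index=False)
            scan = spectral_heritability_scan(kept, kept_ref)
            scan.to_csv(out / "spectral_heritability.csv", index=False)
            bundle["trait_heritability"] = trait_h2
            bundle["spectral_heritability"] = scan

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return bundle
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise type(exc)(f"pipeline failed in stage {failed!r}: {exc}") from exc
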