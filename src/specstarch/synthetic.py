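"""Synthetic multi-trial field designs, starch phenotypes and NIR spectra.

The generator provides ground truth for every downstream stage: plot
values follow the additive random-effects models used for variance
component estimation, and spectra follow a smooth band-mixture forward
model that is exactly linear in starch when noise and scatter are off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .spectra_io import WL_MAX, WL_MIN, ReferenceTable, SpectraSet

__all__ = ["SimulationConfig", "simulate_reference", "simulate_spectra", "plant_outlier"]

_DESIGNS = ("RCBD", "ALPHA_LATTICE")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic field-trial and spectra generator.

    Variances are on the squared-percent scale of the starch trait.  Band
    loadings are reflectance units per percent starch; the water band is
    modeled as negatively coupled to starch (more starch, less free
    water).  With a fixed ``seed`` the output is bit-identical.
    """

    n_trials: int = 2
    genotypes_per_trial: int = 100
    shared_genotype_fraction: float = 0.2
    design: str | Sequence[str] = "RCBD"
    n_reps: int = 2
    blocks_per_rep: int = 5
    starch_mean: float = 25.0
    var_g: float = 30.0
    var_rep: float = 1.0
    var_block: float = 1.0
    var_e: float = 2.0
    band_centers: tuple[float, ...] = (880.0, 912.0, 960.0)
    band_widths: tuple[float, ...] = (15.0, 15.0, 10.0)
    band_loadings: tuple[float, ...] = (0.004, 0.003, 0.0035)
    water_band_center: float = 975.0
    water_band_width: float = 12.0
    water_level: float = 0.15
    water_per_starch: float = 0.002
    baseline_level: float = 0.30
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 0.002
    # Within-plot scan-to-scan jitter is not reported anywhere; defaults to
    # 10% of noise_sd and is independently configurable.
    scan_noise_sd: float | None = None
    scans_per_sample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_centers = tuple(float(c) for c in self.band_centers)
        self.band_widths = tuple(float(w) for w in self.band_widths)
        self.band_loadings = tuple(float(l) for l in self.band_loadings)
        if self.scan_noise_sd is None:
            self.scan_noise_sd = 0.1 * self.noise_sd
        self.validate()

    def validate(self) -> None:
        if self.n_trials < 1 or self.genotypes_per_trial < 1 or self.n_reps < 1:
            raise ConfigError("counts must be positive")
        if not 0.0 <= self.shared_genotype_fraction <= 1.0:
            raise ConfigError("shared_genotype_fraction must lie in [0, 1]")
        for name in ("var_g", "var_rep", "var_block", "var_e"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for d in self.designs():
            if d not in _DESIGNS:
                raise ConfigError(f"unknown design {d!r}; expected one of {_DESIGNS}")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_loadings)):
            raise ConfigError("band_centers/band_widths/band_loadings must have equal length")
        if any(w <= 0 for w in self.band_widths) or self.water_band_width <= 0:
            raise ConfigError("band widths must be positive")
        if self.blocks_per_rep < 1 or self.scans_per_sample < 1:
            raise ConfigError("blocks_per_rep and scans_per_sample must be >= 1")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd", "scan_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def designs(self) -> list[str]:
        if isinstance(self.design, str):
            return [self.design] * self.n_trials
        designs = list(self.design)
        if len(designs) != self.n_trials:
            raise ConfigError("per-trial design list must have n_trials entries")
        return designs

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(WL_MIN, WL_MAX + 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def _trial_ids(n: int) -> list[str]:
    return [f"T{i + 1:02d}" for i in range(n)]


def simulate_reference(config: SimulationConfig) -> ReferenceTable:
    """Draw plot-level starch values from the configured random-effects model.

    RCBD trials: value = mean + genotype + block + residual, one complete
    block per replicate.  Alpha-lattice trials add a replicate effect with
    incomplete blocks nested inside replicates.  A ``shared_genotype_fraction``
    of each trial's genotypes is drawn from a pool common to all trials,
    with genotype effects shared across trials.
    """
    rng = np.random.default_rng(config.seed)
    n_shared = int(round(config.shared_genotype_fraction * config.genotypes_per_trial))
    shared_pool = [f"G{i + 1:04d}" for i in range(n_shared)]

    genotype_effects: dict[str, float] = {}

    def effect(genotype: str) -> float:
        if genotype not in genotype_effects:
            genotype_effects[genotype] = rng.normal(0.0, math.sqrt(config.var_g))
        return genotype_effects[genotype]

    rows = []
    next_unique = n_shared + 1
    for trial_id, design in zip(_trial_ids(config.n_trials), config.designs()):
        genotypes = list(shared_pool)
        while len(genotypes) < config.genotypes_per_trial:
            genotypes.append(f"G{next_unique:04d}")
            next_unique += 1
        for g in genotypes:
            effect(g)

        rep_effects = rng.normal(0.0, math.sqrt(config.var_rep), size=config.n_reps)
        for rep in range(1, config.n_reps + 1):
            if design == "RCBD":
                # One complete block per replicate; the block effect carries
                # the var_block component and rep labels mirror blocks.
                block_effect = rng.normal(0.0, math.sqrt(config.var_block))
                order = rng.permutation(len(genotypes))
                for idx in order:
                    g = genotypes[idx]
                    e = rng.normal(0.0, math.sqrt(config.var_e))
                    value = config.starch_mean + effect(g) + block_effect + e
                    rows.append((trial_id, g, rep, f"B{rep}", design, value))
            else:
                n_blocks = config.blocks_per_rep
                block_effects = rng.normal(0.0, math.sqrt(config.var_block), size=n_blocks)
                order = rng.permutation(len(genotypes))
                for pos, idx in enumerate(order):
                    g = genotypes[idx]
                    b = pos % n_blocks
                    e = rng.normal(0.0, math.sqrt(config.var_e))
                    value = (
                        config.starch_mean
                        + effect(g)
                        + rep_effects[rep - 1]
                        + block_effects[b]
                        + e
                    )
                    rows.append((trial_id, g, rep, f"R{rep}B{b + 1}", design, value))

    frame = pd.DataFrame(
        rows, columns=["trial_id", "genotype_id", "rep", "block", "design", "starch"]
    )
    frame["starch"] = frame["starch"].clip(lower=0.5, upper=99.5)
    frame.insert(
        0,
        "sample_id",
        frame["trial_id"] + ":" + frame["genotype_id"] + ":r" + frame["rep"].astype(str),
    )
    return ReferenceTable(frame)


def _band_matrix(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength starch-band response and water-band shape."""
    wl = config.wavelengths.astype(float)
    response = np.zeros_like(wl)
    for center, width, loading in zip(
        config.band_centers, config.band_widths, config.band_loadings
    ):
        response += loading * np.exp(-0.5 * ((wl - center) / width) ** 2)
    water = np.exp(-0.5 * ((wl - config.water_band_center) / config.water_band_width) ** 2)
    return response, water


def clean_spectrum(starch: float, config: SimulationConfig) -> np.ndarray:
    """Noise- and scatter-free forward model for a single starch value."""
    response, water = _band_matrix(config)
    water_amplitude = config.water_level - config.water_per_starch * starch
    return config.baseline_level + response * starch + water * water_amplitude


def simulate_spectra(reference: ReferenceTable, config: SimulationConfig) -> SpectraSet:
    """Generate ``scans_per_sample`` scan rows per plot.

    Each scan applies an independent multiplicative scatter slope, an
    additive offset, iid wavelength noise and a small scan-level jitter to
    the clean band-mixture spectrum of the plot's starch value.
    """
    if "starch" not in reference.data.columns:
        raise DataError("reference table has no starch values")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    wl = config.wavelengths
    response, water = _band_matrix(config)

    meta_rows = []
    spectra_rows = []
    for row in reference.data.itertuples(index=False):
        starch = float(row.starch)
        if math.isnan(starch):
            raise DataError(f"missing starch value for sample {row.sample_id}")
        water_amplitude = config.water_level - config.water_per_starch * starch
        signal = config.baseline_level + response * starch + water * water_amplitude
        for scan in range(1, config.scans_per_sample + 1):
            slope = rng.normal(0.0, config.scatter_slope_sd)
            offset = rng.normal(0.0, config.scatter_offset_sd)
            noise = rng.normal(0.0, config.noise_sd, size=wl.size)
            jitter = rng.normal(0.0, config.scan_noise_sd, size=wl.size)
            spectra_rows.append((1.0 + slope) * signal + offset + noise + jitter)
            meta_rows.append(
                {
                    "sample_id": row.sample_id,
                    "genotype_id": row.genotype_id,
                    "trial_id": row.trial_id,
                    "rep": row.rep,
                    "block": row.block,
                    "scan_index": scan,
                }
            )
    return SpectraSet(wl, np.array(spectra_rows), pd.DataFrame(meta_rows))


def plant_outlier(spectra: SpectraSet, sample_id, magnitude: float) -> SpectraSet:
    """Shift one sample's spectrum by ``magnitude`` per-wavelength SDs.

    Used as a fixture for the Mahalanobis filter; all other rows are
    untouched and ``magnitude=0`` is the identity.
    """
    mask = (spectra.meta["sample_id"] == sample_id).to_numpy()
    if not mask.any():
        raise DataError(f"unknown sample_id: {sample_id!r}")
    out = spectra.copy()
    sd = np.std(out.reflectance, axis=0, ddof=1)
    out.reflectance[mask] = out.reflectance[mask] + magnitude * sd
    return out
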