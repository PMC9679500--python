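"""Spectral and reference-table containers plus CSV I/O.

The CSV dialect is deliberately simple: UTF-8, comma separated, one header
row.  Metadata columns come first, followed by one column per integer
wavelength (named by the bare nanometre value, e.g. ``740``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, GridError

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "write_reference_csv",
    "average_scans",
    "trim_wavelengths",
    "compute_rsc",
    "summarize_reference",
]

#: Default wavelength grid of the pocket-sized sensor (nm, 1 nm step).
WL_MIN = 740
WL_MAX = 1070

META_COLUMNS = ("sample_id", "genotype_id", "trial_id", "rep", "block", "scan_index")

VALID_DESIGNS = ("RCBD", "ALPHA_LATTICE")


@dataclass
class SpectraSet:
    """A wavelength grid, a reflectance matrix and per-row metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing integer wavelength grid with a uniform step.
    reflectance
        ``(n_rows, n_wavelengths)`` float matrix; no missing values.
    meta
        One row of metadata per spectrum.  ``sample_id`` is required;
        ``genotype_id``, ``trial_id``, ``rep``, ``block`` and
        ``scan_index`` are carried through when present.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=int)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise DataError("reflectance must be a 2-D matrix")
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        wl = self.wavelengths
        if wl.size == 0:
            raise GridError("empty wavelength grid")
        if wl.size > 1:
            steps = np.diff(wl)
            if np.any(steps <= 0):
                raise GridError("wavelength grid must be strictly increasing")
            if np.unique(steps).size > 1:
                raise GridError(f"non-uniform wavelength grid: steps {sorted(set(steps))}")
        if self.reflectance.shape[1] != wl.size:
            raise DataError(
                f"reflectance has {self.reflectance.shape[1]} columns, "
                f"grid has {wl.size} wavelengths"
            )
        if self.reflectance.shape[0] != len(self.meta):
            raise DataError("metadata row count does not match reflectance")
        if "sample_id" not in self.meta.columns:
            raise DataError("metadata must contain a 'sample_id' column")
        if np.isnan(self.reflectance).any():
            raise DataError("reflectance contains missing values")

    # -- conveniences ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def step(self) -> int:
        return int(self.wavelengths[1] - self.wavelengths[0]) if self.wavelengths.size > 1 else 1

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.wavelengths.copy(), self.reflectance.copy(), self.meta.copy())

    def take(self, indices: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.wavelengths.copy(), self.reflectance[idx], self.meta.iloc[idx])

    def select_samples(self, sample_ids: Iterable) -> "SpectraSet":
        wanted = set(sample_ids)
        mask = self.meta["sample_id"].isin(wanted).to_numpy()
        return self.take(np.flatnonzero(mask))

    def to_frame(self) -> pd.DataFrame:
        spec = pd.DataFrame(self.reflectance, columns=[str(w) for w in self.wavelengths])
        return pd.concat([self.meta.reset_index(drop=True), spec], axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraSet):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.allclose(self.reflectance, other.reflectance, rtol=0, atol=1e-12)
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
        )


@dataclass
class ReferenceTable:
    """Plot-level reference phenotype with field-design labels.

    ``data`` has one row per plot with columns ``sample_id``, ``trial_id``,
    ``genotype_id``, ``rep``, ``block``, ``design`` and ``starch`` (% of
    fresh mass, open interval (0, 100)).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "trial_id", "genotype_id", "rep", "block", "design", "starch")

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DataError(f"reference table missing columns: {missing}")
        starch = self.data["starch"].to_numpy(dtype=float)
        if np.isnan(starch).any():
            raise DataError("reference table contains missing starch values")
        if np.any(starch <= 0) or np.any(starch >= 100):
            raise DataError("starch values must lie in the open interval (0, 100)")
        bad = set(self.data["design"].unique()) - set(VALID_DESIGNS)
        if bad:
            raise DataError(f"unknown designs: {sorted(bad)}; expected one of {VALID_DESIGNS}")
        per_trial = self.data.groupby("trial_id")["design"].nunique()
        mixed = per_trial[per_trial > 1]
        if len(mixed):
            raise DataError(f"design must be consistent within trial: {list(mixed.index)}")
        if self.data["sample_id"].duplicated().any():
            raise DataError("duplicate sample_id in reference table")

    @property
    def trials(self) -> list:
        return sorted(self.data["trial_id"].unique().tolist())

    def trial(self, trial_id) -> pd.DataFrame:
        sub = self.data[self.data["trial_id"] == trial_id]
        if sub.empty:
            raise DataError(f"unknown trial: {trial_id!r}")
        return sub.reset_index(drop=True)

    def copy(self) -> "ReferenceTable":
        return ReferenceTable(self.data.copy())


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _split_columns(columns: Sequence[str]) -> tuple[list[str], list[str]]:
    """Partition CSV columns into metadata and integer-named wavelength columns."""
    meta_cols, wl_cols = [], []
    for col in columns:
        name = str(col).strip()
        try:
            int(name)
        except ValueError:
            meta_cols.append(col)
        else:
            wl_cols.append(col)
    return meta_cols, wl_cols


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read and validate a wide spectra CSV.

    Rows with any missing reflectance value are dropped with a warning
    listing the offending ``sample_id`` values.

    Raises
    ------
    GridError
        If the wavelength columns do not form a strictly increasing
        uniform grid.
    DataError
        On duplicate ``(sample_id, scan_index)`` keys or unparseable cells.
    """
    frame = pd.read_csv(path)
    meta_cols, wl_cols = _split_columns(frame.columns)
    if not wl_cols:
        raise GridError(f"no wavelength columns found in {path}")
    wavelengths = np.array([int(str(c).strip()) for c in wl_cols])
    try:
        matrix = frame[wl_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"unparseable reflectance cell in {path}: {exc}") from exc

    bad_rows = np.isnan(matrix).any(axis=1)
    if bad_rows.any():
        dropped = frame.loc[bad_rows, "sample_id"].tolist() if "sample_id" in frame else list(np.flatnonzero(bad_rows))
        warnings.warn(
            f"dropped {int(bad_rows.sum())} row(s) with missing reflectance: {dropped}",
            stacklevel=2,
        )
        frame = frame.loc[~bad_rows]
        matrix = matrix[~bad_rows]

    meta = frame[meta_cols].reset_index(drop=True)
    if "sample_id" in meta.columns:
        key_cols = ["sample_id"] + (["scan_index"] if "scan_index" in meta.columns else [])
        if meta.duplicated(subset=key_cols).any():
            raise DataError(f"duplicate {tuple(key_cols)} keys in {path}")
    return SpectraSet(wavelengths, matrix, meta)


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    spectra.to_frame().to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> ReferenceTable:
    return ReferenceTable(pd.read_csv(path))


def write_reference_csv(reference: ReferenceTable, path: str | Path) -> None:
    reference.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def average_scans(spectra: SpectraSet) -> SpectraSet:
    """Collapse repeated scans to one arithmetic-mean spectrum per sample.

    Metadata other than ``scan_index`` must be constant within a sample;
    conflicting labels raise :class:`DataError`.  Idempotent.
    """
    meta = spectra.meta
    label_cols = [c for c in meta.columns if c not in ("scan_index",)]
    grouped = meta.groupby("sample_id", sort=False)
    for col in label_cols:
        if col == "sample_id":
            continue
        n_values = grouped[col].nunique(dropna=False)
        conflicts = n_values[n_values > 1]
        if len(conflicts):
            raise DataError(
                f"conflicting metadata in column {col!r} for samples {list(conflicts.index)}"
            )

    order = meta["sample_id"].drop_duplicates().tolist()
    codes = meta["sample_id"].map({s: i for i, s in enumerate(order)}).to_numpy()
    n_groups = len(order)
    sums = np.zeros((n_groups, spectra.reflectance.shape[1]))
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    np.add.at(sums, codes, spectra.reflectance)
    means = sums / counts[:, None]

    new_meta = grouped[label_cols].first().loc[order].reset_index(drop=True)
    return SpectraSet(spectra.wavelengths.copy(), means, new_meta)


def trim_wavelengths(spectra: SpectraSet, min_nm: int, max_nm: int) -> SpectraSet:
    """Keep only wavelength columns inside ``[min_nm, max_nm]``."""
    mask = (spectra.wavelengths >= min_nm) & (spectra.wavelengths <= max_nm)
    if not mask.any():
        raise GridError(
            f"trim range [{min_nm}, {max_nm}] does not intersect the grid "
            f"[{spectra.wavelengths[0]}, {spectra.wavelengths[-1]}]"
        )
    return SpectraSet(spectra.wavelengths[mask], spectra.reflectance[:, mask], spectra.meta.copy())


def compute_rsc(dry_starch_mass: float, fresh_mass: float) -> float:
    """Root starch content: dry extracted starch as a percent of fresh mass."""
    dsm = np.asarray(dry_starch_mass, dtype=float)
    fm = np.asarray(fresh_mass, dtype=float)
    if np.any(fm <= 0):
        raise DataError("fresh mass must be positive")
    if np.any(dsm < 0):
        raise DataError("dry starch mass must be non-negative")
    out = 100.0 * dsm / fm
    return float(out) if out.ndim == 0 else out


def summarize_reference(reference: ReferenceTable) -> pd.DataFrame:
    """Per-trial descriptive statistics of the starch phenotype.

    Returns a frame indexed by trial with columns ``min``, ``max``, ``sd``
    (sample SD, n-1), ``cv`` (SD/mean), ``n_plots`` and ``n_genotypes``.
    Trials with a single plot are flagged (``singleton=True``) and their
    dispersion statistics are set to NaN.
    """
    rows = []
    for trial_id, sub in reference.data.groupby("trial_id"):
        starch = sub["starch"].to_numpy(dtype=float)
        singleton = starch.size < 2
        if singleton:
            sd = cv = float("nan")
        else:
            sd = float(np.std(starch, ddof=1))
            cv = sd / float(np.mean(starch))
        rows.append(
            {
                "trial_id": trial_id,
                "min": float(starch.min()),
                "max": float(starch.max()),
                "sd": sd,
                "cv": cv,
                "n_plots": int(starch.size),
                "n_genotypes": int(sub["genotype_id"].nunique()),
                "singleton": singleton,
            }
        )
    return pd.DataFrame(rows).set_index("trial_id")
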