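"""Spectral pretreatment operators: SNV, Savitzky-Golay, gap-segment derivatives.

Thirteen named variants (raw plus twelve combinations) are exposed through
:func:`apply_pretreatment`.  Derivative and smoothing operators drop the
half-window at each spectrum edge instead of padding, so no extrapolated
values ever enter a model; the output grid shrinks accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DataError
from .spectra_io import SpectraSet

__all__ = [
    "PRETREATMENT_IDS",
    "PretreatmentSpec",
    "snv",
    "savitzky_golay",
    "gap_segment_derivative",
    "apply_pretreatment",
]

#: The 13 variants: raw data plus the twelve standard combinations.
PRETREATMENT_IDS = (
    "RAW",
    "SNV",
    "D1",
    "D2",
    "SNV1D",
    "SNV2D",
    "SG",
    "SNVSG",
    "SGD1",
    "SG.D1W5",
    "SG.D1W11",
    "SG.D2W5",
    "SG.D2W11",
)


@dataclass(frozen=True)
class PretreatmentSpec:
    """Resolved parameters for one pretreatment variant.

    ``kind`` is the pipeline: any of ``snv`` (scatter correction first),
    then ``sg`` (Savitzky-Golay) or ``gapseg`` (gap-segment derivative).
    """

    id: str
    snv_first: bool = False
    smoother: str | None = None  # None | "sg" | "gapseg"
    window: int = 0
    polyorder: int = 0
    deriv_order: int = 0
    gap: int = 0
    segment: int = 0

    def __post_init__(self) -> None:
        if self.id not in PRETREATMENT_IDS:
            raise ConfigError(f"unknown pretreatment id {self.id!r}")
        if self.smoother == "sg":
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ConfigError("SG window must be odd and > polyorder")
            if self.deriv_order > self.polyorder:
                raise ConfigError("deriv_order must be <= polyorder")
        if self.smoother == "gapseg":
            if self.gap < 1 or self.segment < 1:
                raise ConfigError("gap and segment must be >= 1")
            if self.gap % 2 == 0:
                raise ConfigError("gap must be odd for a symmetric window")

    @classmethod
    def from_id(cls, pid: str, *, sg_polyorder_d1: int = 2, sg_polyorder_d2: int = 3,
                sgd1_gap: int = 5, sgd1_segment: int = 3) -> "PretreatmentSpec":
        """Build the default spec for a named variant.

        Savitzky-Golay polynomial order defaults to 2 for derivatives <= 1
        and 3 for second derivatives; the gap/segment split of the
        window-11 gap-segment derivative defaults to gap 5, segment 3.
        Both are configurable choices, not fixed by the method names.
        """
        table = {
            "RAW": dict(),
            "SNV": dict(snv_first=True),
            "D1": dict(smoother="gapseg", deriv_order=1, gap=1, segment=1),
            "D2": dict(smoother="gapseg", deriv_order=2, gap=1, segment=1),
            "SNV1D": dict(snv_first=True, smoother="gapseg", deriv_order=1, gap=1, segment=1),
            "SNV2D": dict(snv_first=True, smoother="gapseg", deriv_order=2, gap=1, segment=1),
            "SG": dict(smoother="sg", window=11, polyorder=sg_polyorder_d1, deriv_order=0),
            "SNVSG": dict(snv_first=True, smoother="sg", window=11,
                          polyorder=sg_polyorder_d1, deriv_order=0),
            "SGD1": dict(smoother="gapseg", deriv_order=1, gap=sgd1_gap, segment=sgd1_segment),
            "SG.D1W5": dict(smoother="sg", window=5, polyorder=sg_polyorder_d1, deriv_order=1),
            "SG.D1W11": dict(smoother="sg", window=11, polyorder=sg_polyorder_d1, deriv_order=1),
            "SG.D2W5": dict(smoother="sg", window=5, polyorder=sg_polyorder_d2, deriv_order=2),
            "SG.D2W11": dict(smoother="sg", window=11, polyorder=sg_polyorder_d2, deriv_order=2),
        }
        if pid not in table:
            raise ConfigError(f"unknown pretreatment id {pid!r}")
        return cls(id=pid, **table[pid])


# ---------------------------------------------------------------------------
# Array-level operators
# ---------------------------------------------------------------------------

def _flat(mat: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Zero-variance rows, tolerant of float round-off on constant spectra."""
    scale = np.maximum(np.abs(mat).max(axis=1), 1.0)
    return sd <= 1e-12 * scale


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and scaling.

    Uses the sample SD (n-1).  Raises :class:`DataError` on a
    zero-variance spectrum.
    """
    arr = np.asarray(x, dtype=float)
    one_d = arr.ndim == 1
    mat = np.atleast_2d(arr)
    sd = np.std(mat, axis=1, ddof=1)
    if np.any(_flat(mat, sd)):
        raise DataError("zero-variance spectrum cannot be SNV-transformed")
    out = (mat - np.mean(mat, axis=1, keepdims=True)) / sd[:, None]
    return out[0] if one_d else out


def savitzky_golay(x: np.ndarray, window: int, polyorder: int,
                   deriv_order: int = 0, step: float = 1.0) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative with edge points dropped.

    Each interior point is the ``deriv_order``-th derivative of the local
    least-squares polynomial of degree ``polyorder`` fitted over the
    centred odd ``window``; the half-window at both ends is removed.
    """
    if window % 2 == 0:
        raise ConfigError("window must be odd")
    if polyorder >= window:
        raise ConfigError("polyorder must be < window")
    if deriv_order > polyorder:
        raise ConfigError("deriv_order must be <= polyorder")
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] < window:
        raise ConfigError("window exceeds the number of wavelengths")
    out = savgol_filter(arr, window, polyorder, deriv=deriv_order, delta=step, axis=-1)
    half = window // 2
    return out[..., half:-half]


def gap_segment_derivative(x: np.ndarray, deriv_order: int, gap: int,
                           segment: int, step: float = 1.0) -> np.ndarray:
    """Derivative from the difference of averaged flank segments.

    The first derivative at a point is (mean of the right segment - mean
    of the left segment) divided by the distance ``(gap + segment) * step``
    between segment centres; flanks of ``segment`` points sit either side
    of a central gap of ``gap`` points (total window ``2*segment + gap``).
    Second order applies the rule twice.  Edges are dropped.
    """
    if deriv_order not in (1, 2):
        raise ConfigError("gap-segment derivative supports orders 1 and 2")
    if gap < 1 or segment < 1:
        raise ConfigError("gap and segment must be >= 1")
    if gap % 2 == 0:
        raise ConfigError("gap must be odd for a symmetric window")
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    one_d = np.asarray(x).ndim == 1

    def once(mat: np.ndarray) -> np.ndarray:
        n = mat.shape[1]
        half = segment + gap // 2
        if 2 * half + 1 > n:
            raise ConfigError("gap-segment window exceeds the number of wavelengths")
        g2 = gap // 2
        centers = np.arange(half, n - half)
        left = np.zeros((mat.shape[0], centers.size))
        right = np.zeros_like(left)
        for s in range(1, segment + 1):
            left += mat[:, centers - g2 - s]
            right += mat[:, centers + g2 + s]
        return (right - left) / (segment * (gap + segment) * step)

    out = once(arr)
    if deriv_order == 2:
        out = once(out)
    return out[0] if one_d else out


# ---------------------------------------------------------------------------
# SpectraSet-level application
# ---------------------------------------------------------------------------

def _edge_drop(spec: PretreatmentSpec) -> int:
    if spec.smoother == "sg":
        return spec.window // 2
    if spec.smoother == "gapseg":
        per_pass = spec.segment + spec.gap // 2
        return per_pass * spec.deriv_order
    return 0


def apply_pretreatment(spectra: SpectraSet, spec: PretreatmentSpec | str) -> SpectraSet:
    """Apply one named pretreatment; scatter correction runs first.

    Zero-variance spectra (SNV-undefined) are excluded with a warning.
    The wavelength grid shrinks by the operator's half-window at each edge.
    """
    if isinstance(spec, str):
        spec = PretreatmentSpec.from_id(spec)
    matrix = spectra.reflectance
    meta = spectra.meta
    if spec.snv_first:
        sd = np.std(matrix, axis=1, ddof=1)
        flat = _flat(matrix, sd)
        if flat.any():
            bad = meta.loc[flat, "sample_id"].tolist()
            warnings.warn(f"excluding zero-variance spectra: {bad}", stacklevel=2)
            matrix = matrix[~flat]
            meta = meta.loc[~flat]
        matrix = snv(matrix)

    step = float(spectra.step)
    if spec.smoother == "sg":
        matrix = savitzky_golay(matrix, spec.window, spec.polyorder, spec.deriv_order, step)
    elif spec.smoother == "gapseg":
        matrix = gap_segment_derivative(matrix, spec.deriv_order, spec.gap, spec.segment, step)

    drop = _edge_drop(spec)
    wl = spectra.wavelengths[drop:-drop] if drop else spectra.wavelengths.copy()
    return SpectraSet(wl, np.ascontiguousarray(matrix, dtype=float), meta.copy())
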