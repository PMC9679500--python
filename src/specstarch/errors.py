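"""Exception hierarchy shared across the package."""


class SpecStarchError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpecStarchError, ValueError):
    """Invalid configuration (bad variance, design, pretreatment spec...)."""


class DataError(SpecStarchError, ValueError):
    """Malformed or inconsistent input data."""


class GridError(DataError):
    """Wavelength grid is missing, non-uniform or out of range."""


class DesignError(DataError):
    """Field-design structure is inconsistent (e.g. broken block nesting)."""


class FitError(SpecStarchError, RuntimeError):
    """A model could not be fitted (rank-deficient response etc.)."""


class SchemeError(SpecStarchError, ValueError):
    """A cross-validation scheme cannot be built from the given data."""
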