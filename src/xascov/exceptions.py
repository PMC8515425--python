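"""Exception hierarchy shared across the pipeline."""


class XascovError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XascovError, ValueError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(XascovError, ValueError):
    """Data violate a structural invariant (non-finite values, bad shapes)."""


class GridError(XascovError, ValueError):
    """Energy grids are incompatible (mismatch, non-uniform where uniform is required)."""


class RangeError(XascovError, ValueError):
    """A requested energy window or grid lies outside the data range."""


class ConfigError(XascovError, ValueError):
    """A configuration value is inconsistent or out of bounds."""


class DataError(XascovError, ValueError):
    """Data are structurally valid but physically unusable (e.g. edge jump <= 0)."""


class DegeneracyError(XascovError, ValueError):
    """A linear decomposition is ill-conditioned (components indistinguishable)."""


class CoverageError(XascovError, ValueError):
    """A grid does not cover the spectral features it must represent."""


class FitError(XascovError, RuntimeError):
    """Nonlinear least squares failed to converge in all restarts."""


class CalibrationError(XascovError, ValueError):
    """A calibration produced an unphysical value (e.g. dipole integral <= 0)."""
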