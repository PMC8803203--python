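"""Exception hierarchy for tissuelight.

All errors raised by the package derive from :class:`TissueLightError` so
callers can catch the package's failures with a single ``except`` clause.
"""


class TissueLightError(Exception):
    """Base class for all tissuelight errors."""


class InvalidParameterError(TissueLightError, ValueError):
    """A physical parameter is outside its admissible range."""


class NonPhysicalMeasurementError(TissueLightError, ValueError):
    """Measured diffuse fractions violate energy conservation (r_d + t_d >= 1)."""


class DegenerateReflectanceError(TissueLightError, ValueError):
    """Diffuse reflectance is zero or negative; the inversion is undefined."""


class KMInapplicableError(TissueLightError, ValueError):
    """Two-flux (Kubelka-Munk) assumptions violated: medium not scattering-dominated."""


class SpectrumParseError(TissueLightError, ValueError):
    """A spectrum file could not be parsed into a valid trace."""


class CalibrationError(TissueLightError, ValueError):
    """Empty-sphere reference signal unusable for normalization."""


class BandRangeError(TissueLightError, ValueError):
    """Requested integration band does not overlap the measured wavelength range."""


class GridResolutionError(TissueLightError, ValueError):
    """Finite-difference grid spacing too coarse for the optical length scale."""


class GridDomainError(TissueLightError, ValueError):
    """Finite-difference domain too small relative to the penetration depth."""


class StageError(TissueLightError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
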