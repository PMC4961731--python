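"""Exception hierarchy for spinecarve."""


class SpinecarveError(Exception):
    """Base class for all spinecarve errors."""


class DimensionalityError(SpinecarveError, ValueError):
    """An image is not a 3D scalar volume."""


class ConfigError(SpinecarveError, ValueError):
    """Invalid configuration value or file."""


class EmptyMaskError(SpinecarveError, ValueError):
    """An operation that requires a non-empty mask received an empty one."""


class DegenerateInputError(SpinecarveError, ValueError):
    """Input carries no usable signal (e.g. constant intensities)."""


class DegenerateClassError(SpinecarveError, RuntimeError):
    """A class is absent from a class sequence; ML estimates are undefined.

    Raised by :func:`spinecarve.hmc.ml_estimate` so the SEM loop can resample.
    """
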