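"""Exception types shared across the package."""


class MFKineticsError(Exception):
    """Base class for package errors."""


class InputError(MFKineticsError, ValueError):
    """Invalid data passed to an operation (bad shapes, empty input, bad bounds)."""


class ConfigurationError(MFKineticsError, ValueError):
    """Invalid configuration value (unknown kind, inconsistent thresholds)."""


class FitError(MFKineticsError, RuntimeError):
    """A regression could not be performed (too few usable points)."""


class DegenerateSeriesError(MFKineticsError, RuntimeError):
    """The series carries no fluctuation signal (e.g. all segments detrend to zero)."""
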