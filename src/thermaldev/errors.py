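"""Exception hierarchy.

Errors are split so callers (and the CLI exit codes) can distinguish bad
input data from computations that are well-posed but unanswerable with the
data at hand.
"""


class ThermalDevError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermalDevError, ValueError):
    """Input data violates a schema or an invariant (bad CSV row, negative
    duration, non-increasing timestamps, ...)."""


class DegenerateGeometryError(ThermalDevError):
    """The regression geometry is unidentifiable: fewer than three points,
    a single temperature, or zero sample covariance on the transform."""


class NoThermalResponseError(ThermalDevError):
    """The rate regression produced a non-positive slope: development rate
    does not increase with temperature in these data."""


class InsufficientRecordError(ThermalDevError):
    """The temperature record is too short for the observed stage to have
    been reached at any time within its span."""


class ExtrapolationWarning(UserWarning):
    """Part of the requested interval lies outside the temperature record;
    the nearest reading was held constant over the gap."""
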