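"""Exception hierarchy for radonmetry.

All package-specific failures derive from :class:`RadonmetryError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class RadonmetryError(Exception):
    """Base class for all radonmetry domain errors."""


class InvalidIntervalError(RadonmetryError, ValueError):
    """Integration interval is not a positive multiple of the registration step."""


class DataCompletenessError(RadonmetryError, ValueError):
    """Series is not a complete year-long record (too many gaps or wrong length)."""


class SpotMeasurementError(RadonmetryError, ValueError):
    """Test duration is below the shortest duration with a controlled temporal
    uncertainty (2 days); spot measurements cannot support conformity assessment."""


class NoSignalError(RadonmetryError, ValueError):
    """Gross rate does not exceed background: the device cannot be calibrated."""


class YlcmParseError(RadonmetryError, ValueError):
    """Malformed year-long continuous measurement file."""
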