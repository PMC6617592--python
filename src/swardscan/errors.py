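"""Exception hierarchy for swardscan.

All package-specific failures derive from :class:`SwardScanError` so callers
can distinguish pipeline problems from programming errors.
"""


class SwardScanError(Exception):
    """Base class for all swardscan errors."""


class FormatError(SwardScanError):
    """A scan-stream or table file violates the on-disk dialect."""


class GeometryError(SwardScanError):
    """Stream or window geometry is inconsistent (odometer order, overlaps...)."""


class ParameterError(SwardScanError):
    """A configuration or operation parameter is out of its valid domain."""


class CoverageError(SwardScanError):
    """A stream is too short to cover the configured scan length."""


class EmptyPlotError(SwardScanError):
    """A plot window contains no valid height samples."""


class SingularFitError(ParameterError):
    """A regression cannot be fitted (constant predictor, n < 2)."""
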