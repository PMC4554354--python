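"""Exception hierarchy for the foci-counting pipeline.

Every error raised deliberately by this package derives from
:class:`FociCountError`, so batch drivers can contain per-image failures
without masking genuine programming errors.
"""


class FociCountError(Exception):
    """Base class for all errors raised by focicount."""


class InputError(FociCountError):
    """A file or directory is missing or unreadable."""


class ConfigurationError(FociCountError):
    """A parameter value or combination of parameters is invalid."""


class FormatError(FociCountError):
    """An image decodes, but not to what the pipeline can analyze."""


class DegenerateImageError(FociCountError):
    """Automatic thresholding has no separable histogram (e.g. a constant
    raster); carries the offending file name when known."""


class ComputationError(FociCountError):
    """A measurement was requested on degenerate input (empty ROI,
    non-positive perimeter, zero area)."""


class GenerationError(FociCountError):
    """The synthetic-image generator could not satisfy the requested
    geometry within its retry budget."""


class OutputError(FociCountError):
    """The output location cannot be written."""
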