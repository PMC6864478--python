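"""Typed exceptions shared across the package.

Readers and pipeline stages raise these instead of bare ValueError/OSError so
callers (and the CLI) can distinguish bad parameters, malformed files and
degenerate images.
"""


class OctavaError(Exception):
    """Base class for all package errors."""


class ParameterError(OctavaError, ValueError):
    """An argument violates a documented precondition."""


class ValidationError(OctavaError, ValueError):
    """Data fails a consistency check (bounds, shapes, layouts)."""


class FormatError(OctavaError, ValueError):
    """A file parses but does not match the expected schema."""


class ImageReadError(OctavaError, OSError):
    """A raster file is missing, truncated or undecodable."""


class DegenerateImageError(OctavaError, ValueError):
    """An image has no usable contrast (e.g. constant intensity)."""


class NoFazError(OctavaError, RuntimeError):
    """No avascular-zone candidate survived filtering."""
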