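"""Exception hierarchy.

All package errors derive from :class:`NucblurError` so callers can catch
one type; each also derives from the closest builtin so generic handling
(``except ValueError``) keeps working.
"""


class NucblurError(Exception):
    """Base class for all nucblur errors."""


class FormatError(NucblurError, ValueError):
    """Malformed on-disk data: bad header, missing column, invalid value."""


class BoundsError(NucblurError, IndexError):
    """A coordinate lies outside its chromosome."""


class ShapeError(NucblurError, ValueError):
    """Two genomic objects do not share chromosome names/lengths."""


class DegenerateInputError(NucblurError, ValueError):
    """Input is structurally valid but statistically empty (all-zero track,
    zero-variance scores, empty class, ...)."""


class ConfigError(NucblurError, ValueError):
    """Simulation or model configuration is internally inconsistent."""
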