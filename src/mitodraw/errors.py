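"""Exception hierarchy for mitodraw.

All library errors derive from :class:`MitodrawError` so callers can catch
one base class; parse, edit, layout, and render failures keep distinct types
because the command-line tool maps them to different exit codes.
"""


class MitodrawError(Exception):
    """Base class for all mitodraw errors."""


# --- parsing -------------------------------------------------------------

class ParseError(MitodrawError):
    """Base class for annotation-file parsing failures."""


class UnrecognizedFormat(ParseError):
    """The input text matches none of the supported annotation dialects."""


class MalformedRecord(ParseError):
    """The input matched a dialect but violates its structure."""


class FeatureOutOfBounds(ParseError):
    """A feature's coordinates do not fit the declared genome length."""


class EmptyAnnotation(ParseError):
    """A tabular file contained zero parseable feature lines."""


# --- editing -------------------------------------------------------------

class EditError(MitodrawError):
    """Base class for annotation-editing failures."""


class FeatureNotFound(EditError):
    """No feature with the requested name exists."""


class AmbiguousName(EditError):
    """A rename matched more than one feature."""


class InvalidFeature(EditError):
    """A feature violates its invariants against the genome length."""


class InvalidColor(EditError):
    """A color is not an RGB triple with channels in [0, 255]."""


class LinearTopology(EditError):
    """A circular-only operation was applied to a linear annotation."""


# --- layout / rendering --------------------------------------------------

class LayoutError(MitodrawError):
    """Base class for geometry failures."""


class UnfittableCanvas(LayoutError):
    """Auto-fit would shrink the rings below a drawable size."""


class RenderError(MitodrawError):
    """Base class for rasterization/encoding failures."""


class DpiOutOfRange(RenderError):
    """Requested resolution is outside the supported 100-1000 dpi span."""


class UnsupportedFormat(RenderError):
    """Requested image container is not one of TIFF/JPEG/PNG/BMP."""
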