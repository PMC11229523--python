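"""Exception hierarchy.

Every error raised by fruitmorph derives from :class:`FruitmorphError`, so
callers can catch one type at a CLI boundary while tests can assert on the
specific failure class.
"""


class FruitmorphError(Exception):
    """Base class for all fruitmorph errors."""


class InvalidConfigError(FruitmorphError, ValueError):
    """A configuration value violates its contract (e.g. even median kernel)."""


class DomainError(FruitmorphError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class EmptyMaskError(FruitmorphError, ValueError):
    """A measurement was requested on a mask with no foreground pixels."""


class EmptyContourError(FruitmorphError, ValueError):
    """No closed boundary could be recovered from an edge map."""


class EmptySegmentationError(FruitmorphError, ValueError):
    """Segmentation produced no foreground region."""


class SingularFitError(FruitmorphError, ValueError):
    """The regression design matrix is rank deficient."""


class ModelKeyError(FruitmorphError, KeyError):
    """An unknown key was requested from the reference model registry."""


class UngradableError(FruitmorphError, ValueError):
    """A fruit's mass falls outside every configured size class."""


class CanvasError(FruitmorphError, ValueError):
    """A rendered fruit (ellipse body plus prickles/shadow) exceeds the canvas."""


class SchemaError(FruitmorphError, ValueError):
    """A table is missing required columns or has malformed values."""
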