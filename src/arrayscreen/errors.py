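"""Exception hierarchy for the screen pipeline."""


class ArrayScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(ArrayScreenError):
    """A table violates its documented schema (missing column, bad value,
    duplicate key, unknown enum)."""


class MissingReferenceError(ArrayScreenError):
    """A plate lacks the wells required as the normalization reference."""


class InsufficientControlsError(ArrayScreenError):
    """Too few control wells to fit a control distribution (n < 3)."""


class DegenerateControlsError(ArrayScreenError):
    """Control values have zero sample standard deviation."""


class InsufficientOverlapError(ArrayScreenError):
    """Replicate concordance requires at least 3 shared guides."""


class InsufficientDataError(ArrayScreenError):
    """A group comparison requires at least 3 values per group."""


class NoForegroundError(ArrayScreenError):
    """An image contains no segmentable foreground (e.g. constant pixels)."""


class PlacementError(ArrayScreenError):
    """Synthetic nuclei could not be placed under the layout constraints."""


class DomainError(ArrayScreenError):
    """A parameter is outside its mathematical domain (e.g. rate <= 0)."""
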