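"""Exception hierarchy for mkelm.

All argument/contract violations derive from :class:`ValueError` so that
callers who do not care about the fine distinction can catch one type.
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class ShapeError(InvalidArgumentError):
    """Matrix/vector dimensions are inconsistent."""


class DataError(ValueError):
    """Input data contains non-finite or otherwise unusable values."""


class UndefinedSimilarityError(DataError):
    """A similarity is undefined for the given inputs (e.g. cosine of a zero vector)."""


class DegenerateLabelsError(InvalidArgumentError):
    """Labels do not contain enough classes to fit a classifier."""


class ArchiveError(RuntimeError):
    """A model archive is missing, corrupt, or of an unsupported version."""
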