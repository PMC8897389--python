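"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`GammatcError` so the CLI can
abort with the stage name and the offending identifiers.
"""


class GammatcError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(GammatcError):
    """Inputs disagree with each other (e.g. sample sheet vs count table)."""


class DataError(GammatcError):
    """A value violates a data invariant (e.g. negative pseudocount)."""


class AnnotationError(GammatcError):
    """An identifier is missing from an annotation resource."""


class NormalizationError(GammatcError):
    """Size-factor estimation is impossible on the given matrix."""
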