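"""Exception hierarchy for the mss pipeline."""


class MSSError(Exception):
    """Base class for all mss errors."""


class ParseError(MSSError, ValueError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class StructuralError(MSSError, ValueError):
    """A parsed structure violates an invariant (missing parent, multiple roots...)."""


class UnknownTaxonError(MSSError, KeyError):
    """A taxon id was not found in the taxonomy tree."""


class QueryNotInTaxonomyError(MSSError, LookupError):
    """The query species is absent from the taxonomy; the sequence-based
    (UCO) selection path should be used instead."""


class NoUCOContigsError(MSSError, ValueError):
    """No UCO gene could be identified among the query contigs; taxonomy-based
    selection should be used instead."""


class InsufficientOverlapError(MSSError, ValueError):
    """Fewer than three species are shared between two distance matrices."""


class UndefinedCorrelationError(MSSError, ValueError):
    """A distance matrix has zero variance, so the correlation is undefined."""
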