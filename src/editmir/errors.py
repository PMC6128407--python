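"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`EditmirError`
so callers (and the CLI) can catch one type at the boundary.
"""


class EditmirError(Exception):
    """Base class for all editmir errors."""


class InvalidParameterError(EditmirError, ValueError):
    """A numeric or categorical parameter is outside its allowed range."""


class CapacityError(EditmirError):
    """A planting request exceeds the eligible positions available."""


class ReferenceMismatchError(EditmirError):
    """A record refers to a sequence name or base the reference does not have."""


class MissingSequenceError(ReferenceMismatchError):
    """The reference lacks a sequence name a record requires."""


class CatalogMismatchError(EditmirError):
    """A miRNA identifier is absent from the supplied catalog."""


class MalformedRecordError(EditmirError):
    """A pileup/variant record is structurally invalid (bad base, negative count)."""


class FormatError(EditmirError):
    """An input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConflictError(EditmirError):
    """Merging site lists found the same coordinate with conflicting strands."""


class EmptyGroupError(EditmirError):
    """A summary was requested for a label with no member sites."""


class InfeasiblePlantError(EditmirError):
    """A planted match is impossible (e.g. no 'G' in a seed reverse-complement)."""


class AlphabetError(EditmirError, ValueError):
    """A sequence contains characters outside its allowed alphabet."""


class SequenceLengthError(EditmirError, ValueError):
    """A sequence is too short for the requested operation."""


class ConfigurationError(EditmirError):
    """A run configuration value is invalid or inconsistent."""


class MirnaLookupError(EditmirError, KeyError):
    """A miRNA was looked up in a table that does not contain it."""


class SampleLookupError(EditmirError, KeyError):
    """A sample label was looked up in tables that do not contain it."""


class ModeError(EditmirError):
    """An operation received a match table computed in the wrong count mode."""


class EmptyLibraryError(EditmirError):
    """RPM normalization was requested for a library with zero reads."""


class OutOfBoundsError(EditmirError):
    """A window extends past the end of its reference sequence."""
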