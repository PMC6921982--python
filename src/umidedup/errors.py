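"""Exception hierarchy."""


class UMIDedupError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(UMIDedupError, ValueError):
    """A sequence contains characters outside {A, C, G, T, N} or is empty."""


class LengthMismatchError(UMIDedupError, ValueError):
    """Two sequences (or a table and a query) have differing lengths."""


class IntegrityError(UMIDedupError):
    """A packed representation is internally inconsistent."""


class InvalidQueryError(UMIDedupError, ValueError):
    """A remove_near query violates the index contract."""


class InvalidStateError(UMIDedupError, RuntimeError):
    """An operation requires a fresh (unconsumed) index."""


class ParseError(UMIDedupError, ValueError):
    """A file could not be parsed; carries the offending line number."""


class UMIExtractionError(UMIDedupError, ValueError):
    """A read name does not contain the UMI separator."""
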