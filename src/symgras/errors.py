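"""Exception hierarchy shared across the package.

``FormatError`` and ``DataError`` map to CLI exit status 3 (malformed or
inconsistent data), ``ArgumentError`` to misuse of an operation, and any
other ``SymgrasError`` (or unexpected exception) to exit status 4.
"""


class SymgrasError(Exception):
    """Base class for all package errors."""


class FormatError(SymgrasError):
    """A file does not conform to its declared format."""


class ArgumentError(SymgrasError, ValueError):
    """An operation was called with invalid arguments."""


class BuildError(SymgrasError):
    """A profile HMM could not be built from the given alignment."""


class ScoringError(SymgrasError):
    """A sequence cannot be scored (e.g. empty sequence)."""


class DataError(SymgrasError):
    """Input data are internally inconsistent (missing scores, bad ids...)."""
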