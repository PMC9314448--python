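"""Exception hierarchy.

Exit-code mapping used by the CLI: config errors -> 2, data errors -> 3,
numerical errors -> 4.
"""


class UltraselectError(Exception):
    """Base class for all package errors."""


class ConfigError(UltraselectError):
    """Invalid configuration or parameter value."""


class ParseError(UltraselectError):
    """Malformed input file; message names the offending line."""


class ValidationError(UltraselectError):
    """Input violates a documented precondition or invariant."""


class SchemaError(UltraselectError):
    """Tabular input has missing/unknown columns or duplicated keys."""


class DataIntegrityError(UltraselectError):
    """Cross-file inconsistency (e.g. variant REF does not match FASTA)."""


class NumericalError(UltraselectError):
    """Estimation failed for numerical reasons (degenerate input, domain)."""
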