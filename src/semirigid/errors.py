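"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage = 2, format = 3,
numeric/empty-input = 4).
"""


class SemirigidError(Exception):
    """Base class for all package-specific errors."""


class UsageError(SemirigidError):
    """Invalid parameters or selections (caller error)."""


class FormatError(SemirigidError):
    """Malformed or unsupported input file content."""


class EmptyInputError(SemirigidError):
    """Structurally valid input that contains no usable data."""
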