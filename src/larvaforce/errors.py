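"""Exception hierarchy.

Validation failures are split into format errors (malformed files),
input errors (out-of-contract arguments) and alignment errors (clock
offsets that cannot be corrected), so that callers and the CLI can map
them to distinct exit codes.
"""


class LarvaforceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LarvaforceError):
    """A file or table violates its schema (bad columns, NaN, shuffled time)."""


class InputError(LarvaforceError, ValueError):
    """An argument violates an operation's precondition."""


class AlignmentError(LarvaforceError):
    """Force trace and behaviour track cannot be brought onto a common clock."""
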