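"""Exception hierarchy shared by the library and the command-line tool.

Exit-code contract of the CLI: validation/usage problems exit 1,
capacity refusals exit 2, I/O failures exit 3.
"""


class OrglatticeError(Exception):
    """Base class for all orglattice errors."""

    exit_code = 1


class ValidationError(OrglatticeError):
    """Input violates a documented precondition or invariant."""

    exit_code = 1


class ParseError(ValidationError):
    """Malformed text input; message names the offending line."""


class CapacityError(OrglatticeError):
    """A computation was refused because it would exceed a guard limit."""

    exit_code = 2


class InputOutputError(OrglatticeError):
    """Filesystem-level failure while reading or writing."""

    exit_code = 3
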