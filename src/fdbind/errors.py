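"""Exception types shared across the package."""


class FdbindError(Exception):
    """Base class for all package-specific errors."""


class InputError(FdbindError, ValueError):
    """Raised when user-supplied data violates a documented precondition.

    The message always names the offending entity (row, column, path or
    parameter) so pipeline failures can be traced to their input.
    """
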