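"""Exception hierarchy: input/validation failures versus internal invariant
violations, mapped to distinct process exit codes by the command line."""


class BcescanError(Exception):
    """Base class for package errors."""


class InputError(BcescanError):
    """Invalid or malformed user input (exit code 2 at the command line)."""


class InternalError(BcescanError):
    """An internal invariant was violated (exit code 3 at the command line)."""
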