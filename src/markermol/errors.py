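"""Exception types shared across the package."""


class MarkermolError(Exception):
    """Base class for package errors."""


class FormatError(MarkermolError, ValueError):
    """A file did not conform to the expected text format."""


class ValidationError(MarkermolError, ValueError):
    """An argument violated an operation precondition."""


class InfeasibleError(MarkermolError, ValueError):
    """A geometric construction has no solution (e.g. overstretched linker)."""
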