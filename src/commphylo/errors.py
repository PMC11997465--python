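"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers bad user inputs (exit code 1 in the CLI);
anything else that escapes is a runtime error (exit code 2).
"""


class CommPhyloError(Exception):
    """Base class for all package errors."""


class FormatError(CommPhyloError):
    """A file could not be parsed; the message names the offending token."""


class ValidationError(CommPhyloError):
    """An input violates a documented invariant."""


class UntestableError(CommPhyloError):
    """A statistical test cannot be run on the supplied values."""
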