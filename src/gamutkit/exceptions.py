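"""Exception hierarchy.

All errors derive from :class:`GamutkitError` so callers can catch the
package's failures with a single except clause; each also derives from the
closest builtin (ValueError/RuntimeError) for idiomatic use.
"""


class GamutkitError(Exception):
    """Base class for all gamutkit errors."""


class InputFormatError(GamutkitError, ValueError):
    """A file or table does not satisfy the documented input contract."""


class DomainError(GamutkitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateInputError(GamutkitError, ValueError):
    """A sample is too small or has no variance to support the estimate."""


class OptimizationError(GamutkitError, RuntimeError):
    """The cut optimization has no well-defined maximizer."""
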