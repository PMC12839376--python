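"""Exception hierarchy shared across the package.

Validation failures (bad input rows, inconsistent knowledge-base entries)
and format failures (missing columns, unreadable files) are kept distinct
so the command-line layer can map them to different exit codes.
"""


class DDINetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DDINetError, ValueError):
    """Input content violates a documented constraint (e.g. a self-pair,
    an unknown severity label, a blank drug name)."""


class FormatError(DDINetError, ValueError):
    """A file does not conform to the expected layout (missing header
    columns, unsupported extension)."""


class ConvergenceError(DDINetError, RuntimeError):
    """An iterative numeric routine failed to converge within its
    iteration budget (e.g. eigenvector centrality power iteration)."""
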