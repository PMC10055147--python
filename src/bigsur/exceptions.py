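"""Exception hierarchy.

Validation problems (bad input data, malformed files, impossible
configurations) raise :class:`ValidationError`; numerical failures in the
moment/tail machinery raise :class:`NumericError`.  The CLI maps these to
exit codes 2 and 3 respectively.
"""


class BigSurError(Exception):
    """Base class for package errors."""


class ValidationError(BigSurError, ValueError):
    """Invalid input data or configuration."""


class NumericError(BigSurError, RuntimeError):
    """A numerical routine produced a non-finite or inadmissible result."""
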