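"""Exception hierarchy.

``DataError`` covers everything wrong with user-supplied inputs (parse
failures, alphabet violations, inconsistent dimensions); ``SolverError``
covers failures of the integer-programming backend.  The command-line
layer maps these onto exit codes 2 and 3 respectively.
"""


class RibocontactError(Exception):
    """Base class for all package errors."""


class DataError(RibocontactError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(DataError):
    """A string violates its declared alphabet or invariant."""


class BoundsError(DataError):
    """An index falls outside the dimensions of its contact map."""


class SolverError(RibocontactError):
    """The IP backend failed to return a proven-optimal solution."""
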