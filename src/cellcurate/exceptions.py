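"""Exception hierarchy.

Validation problems (bad values, broken invariants) and I/O/format problems
are kept distinct so the CLI can map them to different exit codes.
"""


class CellcurateError(Exception):
    """Base class for all package errors."""


class ValidationError(CellcurateError):
    """Input violates a documented invariant or precondition."""


class InputError(CellcurateError):
    """A required input (file, directory) is missing."""


class FormatError(CellcurateError):
    """A file exists but cannot be parsed in any supported dialect."""


class BoundaryError(ValidationError):
    """A geometric object leaves the image domain."""


class StateError(ValidationError):
    """An operation is invalid in the current session state."""
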