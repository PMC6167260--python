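"""Exception hierarchy.

CLI exit codes: InputError/SchemaError → 2, CalibrationError → 3.
"""


class MGDbError(Exception):
    """Base class for all package errors."""


class InputError(MGDbError):
    """Invalid value passed to a model operation."""


class SchemaError(InputError):
    """A table violates its schema; message names the offending row/column."""


class CalibrationError(MGDbError):
    """A calibration failed to meet its stated tolerance."""


class ObservedDataRequired(MGDbError):
    """Signals that observed rates must be used instead of the modelled path
    (termination-of-pregnancy group A countries)."""
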