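"""Exception hierarchy for combogate.

All user-facing failures derive from :class:`CombogateError` so the CLI can
map them onto exit codes: validation problems (bad arguments, malformed
files) are :class:`ValidationError` subclasses, numerical/verification
failures are :class:`ComputationError` subclasses.
"""


class CombogateError(Exception):
    """Base class for all combogate errors."""


class ValidationError(CombogateError, ValueError):
    """Invalid argument, option, or input-file content."""


class PanelError(ValidationError):
    """Malformed panel specification."""


class DialectError(ValidationError):
    """CSV dialect could not be determined unambiguously."""


class TableFormatError(ValidationError):
    """Input table does not match the expected schema."""


class RangeError(ValidationError):
    """A percentage value is outside [0, 100]."""


class StructureError(ValidationError):
    """A gating tree is missing nodes or does not match the panel shape."""


class ComputationError(CombogateError):
    """A computation or verification check failed."""
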