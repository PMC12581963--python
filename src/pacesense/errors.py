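"""Exception hierarchy used across the package."""


class PacesenseError(Exception):
    """Base class for all package errors."""


class ParameterError(PacesenseError, ValueError):
    """An argument violates an operation's preconditions."""


class AmplitudeUndefinedError(PacesenseError, ValueError):
    """The VF amplitude of a recording cannot be measured (e.g. all-zero input)."""


class ContractViolationError(PacesenseError, ValueError):
    """An inter-stage contract was violated (e.g. negative samples fed to the event sensor)."""


class FormatError(PacesenseError, ValueError):
    """A file does not conform to the expected on-disk format."""
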