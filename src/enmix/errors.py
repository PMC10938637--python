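"""Exception hierarchy.

Every error raised on a user-facing contract violation derives from
:class:`EnmixError`, so the CLI can map them to exit status 1.
"""


class EnmixError(Exception):
    """Base class for all enmix errors."""


class ParseError(EnmixError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line_number=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line_number is not None:
            loc += f":{line_number}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line_number = line_number


class EmptyInputError(EnmixError):
    """An input contained no usable records."""


class ValidationError(EnmixError):
    """A parsed object violates an internal consistency rule."""


class ParameterError(EnmixError):
    """An argument is outside its documented domain."""


class UnsupportedFunctError(EnmixError):
    """A bonded term uses a function type the mixer cannot perturb."""


class IncompatibleTopologyError(EnmixError):
    """State A and B topologies cannot be mixed (diverging atoms)."""


class UnmixableTermError(EnmixError):
    """A non-harmonic bonded term differs between the two states."""


class NonOverlapError(EnmixError):
    """BAR root-finding failed; phase-space overlap is insufficient."""


class CoverageError(EnmixError):
    """Interval chain does not tile [0, 1] contiguously."""


class UnboundedSystemError(EnmixError):
    """A toy system has a flat direction at the requested coupling value."""


class UnsupportedSystemError(EnmixError):
    """Analytic result requested for a system outside its domain."""


class InsufficientDataError(EnmixError):
    """Too few samples for the requested estimate."""
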