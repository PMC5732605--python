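"""Exception hierarchy for tcnet.

All package errors derive from :class:`TcnetError` so callers can catch one
base class; the subclasses mirror the failure modes of the public operations
(schema validation, configuration of adaptation principles, parameter domains,
numerical integration, file parsing, equilibrium solving).
"""


class TcnetError(Exception):
    """Base class for all tcnet errors."""


class SchemaError(TcnetError):
    """A network specification document violates the schema or an invariant."""


class ConfigError(TcnetError):
    """An adaptation block or reification request is inconsistent."""


class ParameterError(TcnetError):
    """A combination-function parameter is outside its domain."""


class UsageError(TcnetError):
    """An operation was called in a context where it is not defined."""


class IntegrationDivergedError(TcnetError):
    """Euler integration produced a non-finite value."""

    def __init__(self, state: str, time: float):
        self.state = state
        self.time = time
        super().__init__(
            f"integration diverged: state {state!r} became non-finite at t={time:g}"
        )


class InputMismatchError(TcnetError):
    """A trajectory and a network refer to different state ids."""


class NoFixedPointError(TcnetError):
    """g(w) = c(w,..,w) - w has no sign change and no endpoint root on [0,1]."""


class IdentityMapError(TcnetError):
    """c(w,..,w) = w identically: every value is a fixed point."""


class ParseError(TcnetError):
    """A network JSON or trajectory CSV file is malformed."""
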