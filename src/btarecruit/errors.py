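"""Exception hierarchy for btarecruit."""


class BtarecruitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BtarecruitError, ValueError):
    """An input value violates a model precondition (sign, range, units)."""


class ConvergenceError(BtarecruitError, RuntimeError):
    """A numerical solver failed to reach its tolerance.

    Carries the final residual so callers can judge how bad the miss was.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FitError(BtarecruitError, RuntimeError):
    """A regression could not produce a meaningful estimate.

    Raised instead of returning silently bogus parameters, e.g. when a
    titration carries no inhibition signal at all.
    """


class ConfigError(BtarecruitError, ValueError):
    """A run configuration file is malformed; the message names the key."""
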