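"""Exception types shared across the package."""


class TwoStepError(Exception):
    """Base class for package errors."""


class ConfigError(TwoStepError, ValueError):
    """Invalid task / cohort / sampler configuration."""


class InputError(TwoStepError, ValueError):
    """Invalid user-supplied labels or data."""


class ValidationError(TwoStepError, ValueError):
    """A data table violates the trial-record invariants.

    Carries the offending row indices/labels in ``offenders``.
    """

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = offenders if offenders is not None else []


class NumericalError(TwoStepError, ArithmeticError):
    """Non-finite value encountered during likelihood accumulation."""
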