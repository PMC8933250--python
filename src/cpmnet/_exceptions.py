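"""Exception hierarchy for the cpmnet pipeline."""


class CpmError(Exception):
    """Base class for all cpmnet errors."""


class ConfigError(CpmError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InputError(CpmError, ValueError):
    """An input object violates a precondition (dimensions, emptiness, range)."""


class ConstantInputError(InputError):
    """A correlation is undefined because one of the inputs is constant.

    ``mse`` is attached when a mean squared error could still be computed
    alongside the undefined correlation.
    """

    def __init__(self, message: str, mse: float | None = None):
        super().__init__(message)
        self.mse = mse


class SampleSizeError(InputError):
    """Too few observations for the requested statistic."""


class SingularFitError(CpmError):
    """The regression design matrix is rank deficient (collinear features)."""


class EmptyModelError(CpmError):
    """No consensus connections exist for the requested model polarity."""
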