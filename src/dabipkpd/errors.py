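"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when user-supplied values violate a documented precondition."""


class ConfigurationError(ValueError):
    """Raised for inconsistent model/fit configuration (e.g. unknown eta key)."""


class NumericError(RuntimeError):
    """Raised when a numerical routine (integration, factorisation) fails."""


class DegenerateErrorModelError(ValueError):
    """Raised when the combined residual variance is zero at an observation."""


class DatasetError(ValueError):
    """Raised by the dataset reader for malformed rows, naming the row."""
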