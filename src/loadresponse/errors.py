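"""Exception hierarchy for the load-response analysis pipeline."""


class LoadResponseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LoadResponseError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class InputIntegrityError(LoadResponseError):
    """Input data violate a structural contract (duplicate keys, missing rows)."""


class DomainError(LoadResponseError, ValueError):
    """A numeric argument outside the mathematical domain of an operation."""


class GatingIncompleteError(LoadResponseError):
    """Criteria gating was attempted on an incomplete fit table."""

    def __init__(self, gaps):
        self.gaps = list(gaps)
        super().__init__(f"missing marker/timepoint combinations: {self.gaps}")


class InferenceUnavailableError(LoadResponseError):
    """Inference requested from a non-converged or incompatible fit."""


class UndefinedCorrelationError(LoadResponseError):
    """A correlation could not be computed (too few complete pairs)."""
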