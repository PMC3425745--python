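"""Exception hierarchy for model specification and numerical failures."""

__all__ = [
    "ActinfError",
    "ModelSpecificationError",
    "ConfigurationError",
    "NumericalDomainError",
    "IntegrationDivergenceError",
]


class ActinfError(Exception):
    """Base class for all package-specific errors."""


class ModelSpecificationError(ActinfError):
    """A generative model is internally inconsistent (dimensions, precisions)."""


class ConfigurationError(ActinfError):
    """A run configuration is invalid or incomplete."""


class NumericalDomainError(ActinfError):
    """Non-finite or otherwise out-of-domain numerical values encountered."""


class IntegrationDivergenceError(ActinfError):
    """Numerical integration produced a non-finite update."""

    def __init__(self, message: str, coordinate: int | None = None):
        super().__init__(message)
        self.coordinate = coordinate
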