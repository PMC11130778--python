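"""Exception hierarchy shared across the package."""


class CogbatteryError(Exception):
    """Base class for all package errors."""


class RegistryError(CogbatteryError):
    """Corrupt registry data or a lookup of an unknown assessment."""


class ObserverError(CogbatteryError, ValueError):
    """Invalid psychometric-function parameters."""


class EstimationError(CogbatteryError):
    """A threshold estimate was requested from a run that cannot supply one."""


class InsufficientDataError(CogbatteryError):
    """Too few observations for the requested summary or test."""


class FactorInputError(CogbatteryError):
    """The correlation matrix cannot support the requested factor analysis."""


class FactorRetentionError(CogbatteryError):
    """The retention rule kept zero components."""


class ConfigError(CogbatteryError, ValueError):
    """Invalid configuration values (probabilities, marginals, bounds)."""


class PipelineError(CogbatteryError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
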