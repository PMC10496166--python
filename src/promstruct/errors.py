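"""Exception and warning types used across promstruct."""


class PromstructError(Exception):
    """Base class for all promstruct errors."""


class SchemaError(PromstructError):
    """A data file does not match the instrument's column schema."""


class ValidationError(PromstructError):
    """Response codes violate the instrument's category ranges."""


class ConfigurationError(PromstructError):
    """A model, population or pipeline configuration is invalid."""


class IdentificationError(ConfigurationError):
    """A factor model has negative degrees of freedom (under-identified)."""


class EmptyResultError(PromstructError):
    """A filtering step removed every row."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped without meeting its convergence tolerance."""


class HeywoodWarning(UserWarning):
    """A residual variance was driven to its lower bound during fitting."""
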