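"""Exception hierarchy used across the package."""


class FatigueEEGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FatigueEEGError):
    """An invalid simulation or pipeline configuration."""


class ParameterError(FatigueEEGError):
    """An operation received an out-of-contract parameter."""


class FormatError(FatigueEEGError):
    """A file could not be parsed under the named format."""


class DataError(FatigueEEGError):
    """Input data violates a precondition (non-finite samples, wrong shape...)."""
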