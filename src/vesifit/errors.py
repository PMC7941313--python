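"""Exception hierarchy."""


class VesifitError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(VesifitError, ValueError):
    """A model parameter is outside its mathematical domain."""


class InitializationError(VesifitError, RuntimeError):
    """Automatic initialization (e.g. Guinier analysis) failed."""


class FormatError(VesifitError, ValueError):
    """An input file could not be parsed."""


class ConfigError(VesifitError, ValueError):
    """A model configuration file is invalid."""
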