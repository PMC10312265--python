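"""Exception and warning types shared across the package."""


class ConfigurationError(ValueError):
    """A circuit, kernel, or stimulus description is invalid."""


class ConfigurationWarning(UserWarning):
    """A configuration is accepted but parts of it will be ignored."""


class IntegrationError(RuntimeError):
    """The fixed-step integration left the admissible activity range."""


class AnalysisError(ValueError):
    """An analysis operation was applied to unusable input."""
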