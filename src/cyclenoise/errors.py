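"""Exception types shared across the package."""


class CycleNoiseError(Exception):
    """Base class for all package errors."""


class ValidationError(CycleNoiseError, ValueError):
    """A model object or configuration value failed validation.

    The message always names the offending field.
    """


class UnsupportedModelError(CycleNoiseError, ValueError):
    """The requested operation does not support this model variant
    (e.g. closed-form analytics with nonzero degradation)."""


class ConfigError(CycleNoiseError, ValueError):
    """A run configuration file or mapping is malformed."""
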