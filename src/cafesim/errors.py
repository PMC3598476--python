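"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid simulation configuration (bad bounds, unknown keys, ...)."""


class NoCrossingError(RuntimeError):
    """A phase sweep contained no healthy/unhealthy sign change to interpolate."""
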