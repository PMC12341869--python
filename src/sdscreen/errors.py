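"""Exception hierarchy shared across the package."""


class SdscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SdscreenError):
    """Malformed input data (VCF, sex map, depth table, ...)."""


class ConfigError(SdscreenError):
    """Invalid configuration or inconsistent inputs."""
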