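"""Exception types raised across the package."""


class PcotexError(Exception):
    """Base class for package-specific errors."""


class ImageFormatError(PcotexError, ValueError):
    """Unsupported image layout (channel count, bit depth, dimensionality)."""


class EmptyMaskError(PcotexError, ValueError):
    """An analysis region ended up with zero valid pixels."""


class ConfigError(PcotexError, ValueError):
    """Invalid feature or run configuration."""


class SchemaError(PcotexError, KeyError):
    """A named feature plane or model field is missing or mismatched."""


class TrainingCoverageError(PcotexError, ValueError):
    """Training data does not cover all texture classes adequately."""
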