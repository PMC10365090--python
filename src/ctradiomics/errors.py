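"""Exception hierarchy shared across the package."""


class CtRadiomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CtRadiomicsError, ValueError):
    """Invalid configuration value (non-positive count, bad fraction, ...)."""


class FormatError(CtRadiomicsError, IOError):
    """A file could not be parsed as the expected imaging format."""


class GeometryError(CtRadiomicsError, ValueError):
    """Volume/mask geometries disagree (shape, spacing or origin)."""


class DegenerateLesionError(CtRadiomicsError, ValueError):
    """A segmentation is empty or collapses to nothing after processing."""
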